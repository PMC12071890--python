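# sctselect

**Synthetic-CT based photon/proton treatment-modality selection for thoracic
radiotherapy.**

Choosing between photon (VMAT) and proton (IMPT) radiotherapy normally has
to wait for the dedicated planning CT (pCT), because the decision rests on
comparing dose distributions and normal-tissue complication probabilities
(NTCP) computed on it.  `sctselect` implements an expedited alternative: a
3D encoder–decoder network predicts, from the readily available diagnostic
CT (dCT), a deformation vector field (DVF) that maps the diagnostic anatomy
onto a planning-like geometry; warping the dCT by that field yields a
synthetic CT (sCT) on which the photon/proton comparison can run immediately
after diagnosis.  The package is aimed at medical-physics researchers who
want a transparent, fully seeded reference implementation of that workflow —
from preprocessing through the modality verdict — plus the synthetic thorax
cohort generator used to validate it.

## The model in brief

- **sCT synthesis**: a U-Net-style network f maps the preprocessed dCT to a
  displacement field u = f(dCT) (mm, same grid); sCT(x) = dCT(x + u(x)).
  Training minimizes `(1 − SSIM(warp(dCT, u), pCT)) + λ·R(u)` with R the
  diffusion (squared-gradient) regularizer, using Adam.  The network and its
  training loop run on a compact numpy reverse-mode autodiff engine —
  float64, bit-reproducible under a seed, gradient-checked in the tests.
- **Dosimetry**: cumulative DVHs per organ at risk; the compared panel is
  esophagus (mean, V35Gy, V60Gy), total lung (mean, V10Gy, V20Gy), heart
  (mean, max, V30Gy), with ΔDVH = proton − photon evaluated on each CT.
- **Toxicity**: the Lyman–Kutcher–Burman model,
  `Deff = (Σ v_i d_i^{1/n})^n`, `NTCP = Φ((Deff − TD50)/(m·TD50))`, for
  heart pericarditis, lung pneumonitis and esophageal perforation
  (parameters in an overridable YAML file).
- **Verdict**: per endpoint and case, ΔNTCP = NTCP_proton − NTCP_photon on
  sCT and on pCT; negative favors protons.  Endpoint-cases with all four
  NTCP values ≤ 0.05% are excluded as irrelevant; the report gives the sign
  concordance (trend accuracy), Lin's CCC over the paired differences, and
  per-organ |Δ^(sCT−pCT)| summaries.
- **Phantom cohort**: since paired dCT/pCT data are not redistributable, a
  generator produces thorax phantoms with ground-truth masks, smooth
  invertible deformations, curved-bed vs flat-couch acquisition differences,
  protocol HU offsets, contrast and truncation failure modes, and
  photon/proton-like dose fields whose organ-level ordering is controlled —
  so every end-to-end claim is testable against known truth.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```python
from sctselect import pipeline

config = pipeline.PipelineConfig(
    out_dir="run", seed=1, n_cases=4,
    favoring=("proton", "photon", "proton", "proton"),
)
results = pipeline.run_pipeline(config)
report = results["modality_report"].to_dict()
print(f"included {report['n_included']}/{report['n_candidates']} endpoint-cases")
print(f"trend accuracy {report['trend_accuracy_pct']:.1f}%  CCC {report['ccc']:.4f}")
for pair in report["pairs"]:
    print(pair["case"], pair["endpoint"],
          f"dNTCP sCT {pair['delta_ntcp_sct_pct']:+.3f}%",
          f"pCT {pair['delta_ntcp_pct_pct']:+.3f}%",
          "->", pair["preferred_pct"])
```

Output (seed 1):

```
included 4/12 endpoint-cases
trend accuracy 100.0%  CCC 0.9967
case00 lung_pneumonitis dNTCP sCT -0.082% pCT -0.102% -> proton
case01 lung_pneumonitis dNTCP sCT +0.191% pCT +0.191% -> photon
case02 lung_pneumonitis dNTCP sCT -0.104% pCT -0.102% -> proton
case03 lung_pneumonitis dNTCP sCT -0.106% pCT -0.102% -> proton
```

Four synthetic cases run end to end: couch removal, histogram matching,
rigid alignment, network training and sCT prediction, photon/proton dose
fields, DVH and NTCP comparison.  Case 1 was generated with a
photon-favoring dose pair and cases 0/2/3 with proton-favoring ones; the
sCT-based differences recover the engineered sign in every included
endpoint-case (trend accuracy 100%), and the pericarditis/perforation
endpoints fall below the 0.05% relevance threshold at this geometry (4 of
12 candidates included).  Rerunning with the same config reproduces the
report byte-for-byte.

The same workflow is scriptable from the shell:

```bash
sct-select demo --out demo --seed 1     # write a synthetic case + config
sct-select run --config demo/config.yaml
sct-select evaluate --a run/volumes/case00_sct.nii.gz --b pct.nii.gz
```

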