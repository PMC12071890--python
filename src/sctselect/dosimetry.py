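"""Cumulative DVH computation and the proton-vs-photon DVH comparison.

The modality comparison looks at a fixed panel of organ-at-risk DVH metrics
-- esophagus (mean, V35Gy, V60Gy), total lung (mean, V10Gy, V20Gy), heart
(mean, max, V30Gy) -- and, for each metric, the proton-minus-photon
difference computed separately on the synthetic CT and the planning CT:

    dDVH_sCT = DVH_proton_sCT - DVH_photon_sCT
    dDVH_pCT = DVH_proton_pCT - DVH_photon_pCT
    dDVH_(sCT-pCT) = dDVH_sCT - dDVH_pCT

Matching signs of dDVH_sCT and dDVH_pCT mean both CTs point at the same
advantageous modality for that metric.

VxGy is the percentage of the structure volume receiving >= x Gy (relative
volumes, closed threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DoseVolume, StructureMask
from .metrics import ccc

__all__ = [
    "DVHCurve",
    "DeltaDVH",
    "STANDARD_PANEL",
    "compute_dvh",
    "dvh_metric",
    "build_panel",
    "delta_dvh_panel",
    "agreement_summary",
]

# structure -> metric names, as compared in the modality-selection workflow
STANDARD_PANEL: dict[str, tuple[str, ...]] = {
    "esophagus": ("mean", "V35Gy", "V60Gy"),
    "total_lung": ("mean", "V10Gy", "V20Gy"),
    "heart": ("mean", "max", "V30Gy"),
}


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve on uniform dose bins.

    ``cum_fraction[i]`` is the fraction of the structure volume receiving at
    least ``edges[i]`` Gy; it is 1 at 0 Gy, non-increasing, and 0 above the
    maximum dose.
    """

    edges: np.ndarray  # Gy, uniform width, ascending
    cum_fraction: np.ndarray  # same length as edges
    structure: str = ""
    volume_cc: float = 0.0

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.float64)
        self.cum_fraction = np.asarray(self.cum_fraction, dtype=np.float64)
        if self.edges.shape != self.cum_fraction.shape or self.edges.ndim != 1:
            raise ValueError("edges and cum_fraction must be equal-length 1D arrays")
        if np.any(np.diff(self.cum_fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0]) if self.edges.size > 1 else 0.0

    def differential(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin-center doses, fractional volumes) of the differential DVH."""
        v = -np.diff(self.cum_fraction)
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        return centers, v


def compute_dvh(dose: DoseVolume, mask: StructureMask, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH of the voxel dose multiset inside ``mask``."""
    if dose.shape != mask.shape:
        raise ValueError(f"dose grid {dose.shape} does not match mask grid {mask.shape}")
    if not mask.data.any():
        raise ValueError(f"empty structure mask {mask.name!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = np.asarray(dose.data, dtype=np.float64)[mask.data]
    if np.any(d < 0):
        raise ValueError("negative dose values")
    top = (np.floor(d.max() / bin_width) + 2) * bin_width
    edges = np.arange(0.0, top + 0.5 * bin_width, bin_width)
    # fraction of voxels with dose >= edge (closed threshold)
    counts = np.searchsorted(np.sort(d), edges - 1e-12 * max(1.0, top), side="left")
    cum = 1.0 - counts / d.size
    return DVHCurve(edges, cum, structure=mask.name, volume_cc=mask.volume_cc)


def dvh_metric(curve: DVHCurve, kind: str) -> float:
    """Evaluate one DVH metric: ``mean`` / ``max`` (Gy) or ``VxGy`` (%)."""
    if kind == "mean":
        centers, v = curve.differential()
        return float(np.sum(centers * v))
    if kind == "max":
        nz = np.nonzero(curve.cum_fraction > 0)[0]
        return float(curve.edges[nz[-1]]) if nz.size else 0.0
    if kind.startswith("V") and kind.endswith("Gy"):
        x = float(kind[1:-2])
        if x < 0:
            raise ValueError("VxGy threshold must be non-negative")
        if x >= curve.edges[-1]:
            return 0.0
        return float(np.interp(x, curve.edges, curve.cum_fraction) * 100.0)
    raise ValueError(f"unknown DVH metric kind {kind!r}")


def build_panel(
    dose: DoseVolume,
    masks: dict[str, StructureMask],
    panel: dict[str, tuple[str, ...]] | None = None,
    bin_width: float = 0.1,
) -> dict[str, dict[str, float]]:
    """Evaluate the OAR metric panel for one plan (one dose grid)."""
    panel = panel or STANDARD_PANEL
    out: dict[str, dict[str, float]] = {}
    for structure, kinds in panel.items():
        if structure not in masks:
            raise KeyError(f"missing structure mask {structure!r}")
        curve = compute_dvh(dose, masks[structure], bin_width=bin_width)
        out[structure] = {k: dvh_metric(curve, k) for k in kinds}
    return out


@dataclass
class DeltaDVH:
    structure: str
    metric: str
    delta_sct: float  # proton - photon on sCT
    delta_pct: float  # proton - photon on pCT
    case: str = ""

    @property
    def delta_sct_minus_pct(self) -> float:
        return self.delta_sct - self.delta_pct

    @property
    def concordant(self) -> bool:
        # a zero difference prefers neither modality: concordant with either sign
        if self.delta_sct == 0.0 or self.delta_pct == 0.0:
            return True
        return (self.delta_sct > 0) == (self.delta_pct > 0)


def _flatten(panel: dict[str, dict[str, float]]) -> dict[tuple[str, str], float]:
    return {(s, m): v for s, d in panel.items() for m, v in d.items()}


def delta_dvh_panel(
    proton_sct: dict[str, dict[str, float]],
    photon_sct: dict[str, dict[str, float]],
    proton_pct: dict[str, dict[str, float]],
    photon_pct: dict[str, dict[str, float]],
    case: str = "",
) -> list[DeltaDVH]:
    """Per-metric proton-minus-photon differences on each CT."""
    flats = [_flatten(p) for p in (proton_sct, photon_sct, proton_pct, photon_pct)]
    keys = set(flats[0])
    for f in flats[1:]:
        if set(f) != keys:
            missing = sorted(keys.symmetric_difference(f))
            raise ValueError(f"metric sets differ between panels: {missing}")
    out = []
    for s, m in sorted(keys):
        out.append(
            DeltaDVH(
                structure=s,
                metric=m,
                delta_sct=flats[0][(s, m)] - flats[1][(s, m)],
                delta_pct=flats[2][(s, m)] - flats[3][(s, m)],
                case=case,
            )
        )
    return out


def agreement_summary(deltas: list[DeltaDVH]) -> dict:
    """Modality-preference agreement between sCT- and pCT-based differences.

    Returns the concordant/total counts and rate (%), Lin's CCC over the
    paired (dDVH_sCT, dDVH_pCT) values, and the mean |dDVH_(sCT-pCT)| per
    structure.
    """
    if not deltas:
        raise ValueError("no DVH differences to summarize")
    n = len(deltas)
    n_conc = sum(d.concordant for d in deltas)
    summary = {
        "n_total": n,
        "n_concordant": n_conc,
        "n_discordant": n - n_conc,
        "agreement_rate_pct": 100.0 * n_conc / n,
        "ccc": ccc([d.delta_sct for d in deltas], [d.delta_pct for d in deltas])
        if n >= 2
        else None,
    }
    by_structure: dict[str, list[float]] = {}
    for d in deltas:
        by_structure.setdefault(d.structure, []).append(abs(d.delta_sct_minus_pct))
    summary["mean_abs_delta_by_structure"] = {
        s: float(np.mean(v)) for s, v in sorted(by_structure.items())
    }
    return summary
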