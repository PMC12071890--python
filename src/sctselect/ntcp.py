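"""LKB normal-tissue complication probability and modality selection.

The Lyman-Kutcher-Burman model reduces an inhomogeneous organ dose
distribution to an effective uniform dose

    Deff = (sum_i v_i d_i^(1/n))^n        (Kutcher-Burman effective volume)

over the differential DVH (fractional volumes v_i summing to 1), then maps it
through a probit dose-response:

    NTCP = Phi((Deff - TD50) / (m * TD50))

with Phi the standard normal CDF.  TD50 is the uniform whole-organ dose giving
50% complication probability, m the slope, and n in (0, 1] the volume effect
(n = 1: Deff is the mean dose, serial-parallel organs like lung; n -> 0: Deff
approaches the maximum dose, serial organs like esophagus).

Modality selection compares, per endpoint and case,

    dNTCP_sCT = NTCP_proton_sCT - NTCP_photon_sCT
    dNTCP_pCT = NTCP_proton_pCT - NTCP_photon_pCT

A negative difference favors the proton plan.  Endpoint-cases where all four
NTCP values are negligible (none above a 0.05% relevance threshold) are
excluded as irrelevant to the decision.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.special import ndtr

from .dosimetry import DVHCurve
from .metrics import ccc

__all__ = [
    "LKBParams",
    "NTCPResult",
    "EndpointCaseNTCP",
    "ModalityReport",
    "ENDPOINT_STRUCTURES",
    "load_lkb_params",
    "geud",
    "lkb_ntcp",
    "delta_ntcp",
    "relevance_filter",
    "modality_verdict",
]

# endpoint name -> organ-at-risk structure it is evaluated on
ENDPOINT_STRUCTURES = {
    "heart_pericarditis": "heart",
    "lung_pneumonitis": "total_lung",
    "esophagus_perforation": "esophagus",
}


@dataclass(frozen=True)
class LKBParams:
    endpoint: str
    td50_gy: float
    m: float
    n: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.td50_gy <= 0:
            raise ValueError("TD50 must be positive")
        if self.m <= 0:
            raise ValueError("slope m must be positive")
        if not 0 < self.n <= 1:
            raise ValueError("volume exponent n must lie in (0, 1]")


def load_lkb_params(path: str | Path | None = None) -> dict[str, LKBParams]:
    """Load endpoint -> LKB parameter map; defaults ship with the package."""
    if path is None:
        ref = importlib.resources.files("sctselect").joinpath("data/lkb_defaults.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return {
        name: LKBParams(
            endpoint=name,
            td50_gy=float(d["TD50_gy"]),
            m=float(d["m"]),
            n=float(d["n"]),
            source=str(d.get("source", "")),
        )
        for name, d in raw.items()
    }


def geud(dvh: DVHCurve, n: float) -> float:
    """Generalized equivalent uniform dose (power mean with exponent 1/n)."""
    if n <= 0:
        raise ValueError("volume exponent n must be positive")
    d, v = dvh.differential()
    total = v.sum()
    if total <= 0:
        raise ValueError("empty DVH curve")
    v = v / total
    return float(np.sum(v * np.power(d, 1.0 / n)) ** n)


def lkb_ntcp(dvh: DVHCurve, params: LKBParams) -> float:
    """LKB complication probability for one plan/structure (as probability)."""
    deff = geud(dvh, params.n)
    t = (deff - params.td50_gy) / (params.m * params.td50_gy)
    return float(ndtr(t))


@dataclass(frozen=True)
class NTCPResult:
    endpoint: str
    modality: str  # "photon" | "proton"
    ct_source: str  # "sCT" | "pCT"
    deff_gy: float
    ntcp: float  # probability in [0, 1]

    @property
    def ntcp_pct(self) -> float:
        return 100.0 * self.ntcp


def delta_ntcp(proton: NTCPResult, photon: NTCPResult) -> float:
    """Signed NTCP_proton - NTCP_photon (probability scale)."""
    if proton.endpoint != photon.endpoint or proton.ct_source != photon.ct_source:
        raise ValueError(
            f"mismatched comparison: {proton.endpoint}/{proton.ct_source} vs "
            f"{photon.endpoint}/{photon.ct_source}"
        )
    if proton.modality != "proton" or photon.modality != "photon":
        raise ValueError("arguments must be (proton, photon) results")
    return proton.ntcp - photon.ntcp


@dataclass
class EndpointCaseNTCP:
    """The four NTCP values (2 modalities x 2 CTs) for one endpoint and case."""

    case: str
    endpoint: str
    values: dict[tuple[str, str], float]  # (modality, ct_source) -> probability

    KEYS = (("photon", "sCT"), ("proton", "sCT"), ("photon", "pCT"), ("proton", "pCT"))

    def __post_init__(self) -> None:
        missing = [k for k in self.KEYS if k not in self.values]
        if missing:
            raise ValueError(f"missing NTCP values for {missing}")

    @property
    def max_ntcp(self) -> float:
        return max(self.values[k] for k in self.KEYS)

    @property
    def delta_sct(self) -> float:
        return self.values[("proton", "sCT")] - self.values[("photon", "sCT")]

    @property
    def delta_pct(self) -> float:
        return self.values[("proton", "pCT")] - self.values[("photon", "pCT")]

    @property
    def delta_sct_minus_pct(self) -> float:
        return self.delta_sct - self.delta_pct

    @property
    def concordant(self) -> bool:
        if self.delta_sct == 0.0 or self.delta_pct == 0.0:
            return True
        return (self.delta_sct > 0) == (self.delta_pct > 0)

    def preferred(self, ct_source: str) -> str:
        d = self.delta_sct if ct_source == "sCT" else self.delta_pct
        if d < 0:
            return "proton"
        if d > 0:
            return "photon"
        return "either"


def relevance_filter(
    results: list[EndpointCaseNTCP], threshold_pct: float = 0.05
) -> tuple[list[EndpointCaseNTCP], list[EndpointCaseNTCP]]:
    """Split endpoint-cases into (included, excluded) by peak NTCP.

    An endpoint-case is included iff ANY of its four NTCP values exceeds the
    threshold (default 0.05%); requiring all four would drop one side of a
    paired comparison.  Set ``threshold_pct=0`` to keep everything.
    """
    if threshold_pct < 0:
        raise ValueError("threshold must be non-negative")
    thr = threshold_pct / 100.0
    included = [r for r in results if r.max_ntcp > thr]
    excluded = [r for r in results if r.max_ntcp <= thr]
    return included, excluded


@dataclass
class ModalityReport:
    """Modality-selection verdict with trend-concordance statistics."""

    included: list[EndpointCaseNTCP]
    excluded: list[EndpointCaseNTCP]
    threshold_pct: float

    def to_dict(self) -> dict:
        inc = self.included
        n = len(inc)
        per_pair = [
            {
                "case": r.case,
                "endpoint": r.endpoint,
                "ntcp_pct": {f"{m}_{c}": 100.0 * r.values[(m, c)] for m, c in r.KEYS},
                "delta_ntcp_sct_pct": 100.0 * r.delta_sct,
                "delta_ntcp_pct_pct": 100.0 * r.delta_pct,
                # recompute on the reported scale so the identity is bit-exact
                "delta_sct_minus_pct_pct": 100.0 * r.delta_sct - 100.0 * r.delta_pct,
                "concordant": r.concordant,
                "preferred_sct": r.preferred("sCT"),
                "preferred_pct": r.preferred("pCT"),
            }
            for r in inc
        ]
        by_endpoint: dict[str, list[EndpointCaseNTCP]] = {}
        for r in inc:
            by_endpoint.setdefault(r.endpoint, []).append(r)
        endpoint_summary = {}
        for ep, rs in sorted(by_endpoint.items()):
            diffs = [100.0 * r.delta_sct_minus_pct for r in rs]
            prefs = [r.preferred("pCT") for r in rs]
            endpoint_summary[ep] = {
                "n": len(rs),
                "mean_abs_delta_sct_minus_pct_pct": float(np.mean(np.abs(diffs))),
                "median_delta_sct_minus_pct_pct": float(np.median(diffs)),
                "verdict": (
                    "proton preferred"
                    if prefs.count("proton") > prefs.count("photon")
                    else "photon preferred"
                    if prefs.count("photon") > prefs.count("proton")
                    else "no clear preference"
                ),
            }
        out = {
            "threshold_pct": self.threshold_pct,
            "n_candidates": n + len(self.excluded),
            "n_included": n,
            "n_excluded": len(self.excluded),
            "excluded": [
                {"case": r.case, "endpoint": r.endpoint, "max_ntcp_pct": 100.0 * r.max_ntcp}
                for r in self.excluded
            ],
            "pairs": per_pair,
            "endpoint_summary": endpoint_summary,
        }
        if n == 0:
            out["status"] = "no relevant endpoints"
            out["trend_accuracy_pct"] = None
            out["ccc"] = None
        else:
            out["status"] = "ok"
            out["trend_accuracy_pct"] = 100.0 * sum(r.concordant for r in inc) / n
            out["ccc"] = (
                ccc([r.delta_sct for r in inc], [r.delta_pct for r in inc]) if n >= 2 else None
            )
        return out


def modality_verdict(
    results: list[EndpointCaseNTCP], threshold_pct: float = 0.05
) -> ModalityReport:
    """Apply the relevance filter and assemble the modality-selection report."""
    included, excluded = relevance_filter(results, threshold_pct)
    return ModalityReport(included=included, excluded=excluded, threshold_pct=threshold_pct)
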