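"""DVH metrics, plan-quality indices, NTCP models and paired comparison.

`DVHCurve` is the single source of Dx%/Dycc/VxGy/Dmean metrics used by the
robustness, interplay and reporting layers.  Quantile-type metrics use
linear interpolation between sorted voxel doses; absolute-volume metrics
(D0.04cc, D1cc) go through the same interpolation on the cumulative
volume axis.

NTCP models are logistic: p = 1 / (1 + exp(-S)) with a linear predictor
S = b0 + b1 * (mean organ dose) + sum(covariate terms).  The three default
endpoints (2-year mortality from mean heart dose, grade >= 2 pneumonitis
from mean lung dose, grade >= 2 dysphagia from mean esophageal dose)
ship with representative published-order coefficients; they are editable
model parameters, not clinical constants, and any serious use should
substitute the coefficients of the protocol in force.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .volumes import VoxelVolume

__all__ = [
    "DVHCurve",
    "dvh_metrics",
    "conformity_homogeneity_id",
    "NTCPModelParams",
    "default_ntcp_models",
    "ntcp",
    "compare_plans",
]


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one ROI under one dose."""

    roi_name: str
    doses_gy: np.ndarray  # per-voxel doses, ascending
    voxel_cc: float

    def __post_init__(self) -> None:
        d = np.sort(np.asarray(self.doses_gy, dtype=float))
        if d.size == 0:
            raise ValueError("empty ROI has no DVH")
        if not np.all(np.isfinite(d)):
            raise ValueError("doses must be finite")
        self.doses_gy = d

    @classmethod
    def from_dose(cls, dose, mask: VoxelVolume, roi_name: str = "") -> "DVHCurve":
        vol = dose.volume if hasattr(dose, "volume") else dose
        if not vol.same_grid(mask):
            raise ValueError("dose and mask grids differ")
        m = mask.values.astype(bool)
        return cls(roi_name, vol.values[m], mask.voxel_volume_cc)

    @property
    def total_cc(self) -> float:
        return len(self.doses_gy) * self.voxel_cc

    def curve(self, bins: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(dose axis, % volume receiving >= dose); nonincreasing, V(0)=100."""
        if bins is None:
            top = float(self.doses_gy[-1]) or 1.0
            bins = np.linspace(0.0, 1.05 * top, 200)
        frac = np.array([np.mean(self.doses_gy >= b) for b in bins]) * 100.0
        return bins, frac

    def d_percent(self, x: float) -> float:
        """Dose received by at least x% of the ROI volume (Gy)."""
        if not (0.0 <= x <= 100.0):
            raise ValueError("percent volume must be in [0, 100]")
        return float(np.quantile(self.doses_gy, 1.0 - x / 100.0))

    def d_cc(self, vol_cc: float) -> float:
        """Dose received by at least ``vol_cc`` cm^3 of the ROI (Gy)."""
        if vol_cc <= 0:
            raise ValueError("query volume must be > 0")
        if vol_cc > self.total_cc + 1e-12:
            raise ValueError(
                f"query volume {vol_cc} cc exceeds ROI volume {self.total_cc:.3f} cc"
            )
        return self.d_percent(100.0 * vol_cc / self.total_cc)

    def v_gy(self, dose_gy: float) -> float:
        """% of the ROI volume receiving at least ``dose_gy``."""
        return float(np.mean(self.doses_gy >= dose_gy) * 100.0)

    def d_mean(self) -> float:
        return float(self.doses_gy.mean())

    _METRIC_RE = re.compile(r"^(D(?P<pct>[\d.]+)%|D(?P<cc>[\d.]+)cc|V(?P<gy>[\d.]+)Gy|Dmean)$")

    def metric(self, query: str) -> float:
        """Evaluate a metric by its clinical-goal-table name."""
        m = self._METRIC_RE.match(query)
        if not m:
            raise ValueError(f"unknown metric syntax {query!r}")
        if query == "Dmean":
            return self.d_mean()
        if m.group("pct") is not None:
            return self.d_percent(float(m.group("pct")))
        if m.group("cc") is not None:
            return self.d_cc(float(m.group("cc")))
        return self.v_gy(float(m.group("gy")))


def dvh_metrics(curve: DVHCurve, queries: list[str]) -> dict[str, float]:
    """Evaluate several metrics of one curve, e.g. ['D98%', 'V30Gy']."""
    return {q: curve.metric(q) for q in queries}


def conformity_homogeneity_id(
    dose,
    structures,
    prescription_gy: float,
    *,
    target_roi: str = "CTV",
    body_roi: str = "Body",
    isodose_fraction: float = 0.95,
    ci_definition: str = "paddick",
) -> dict[str, float]:
    """Homogeneity index, conformity index and body integral dose.

    HI = (D2% - D98%) / D50% on the target (0 = perfectly homogeneous).
    CI (default 'paddick') = TV_PIV^2 / (TV * PIV) at the
    ``isodose_fraction`` x prescription isodose, in [0, 1] with 1 = perfect
    conformity; 'rtog' gives the classic PIV / TV ratio instead.
    ID = sum over body voxels of dose x voxel volume (Gy*cc).
    """
    if prescription_gy <= 0:
        raise ValueError("prescription must be > 0")
    vol = dose.volume if hasattr(dose, "volume") else dose
    tgt = structures[target_roi].values.astype(bool)
    body = structures[body_roi].values.astype(bool)
    if not tgt.any():
        raise ValueError("empty target")

    curve = DVHCurve(target_roi, vol.values[tgt], structures[target_roi].voxel_volume_cc)
    hi = (curve.d_percent(2.0) - curve.d_percent(98.0)) / curve.d_percent(50.0)

    level = isodose_fraction * prescription_gy
    piv = vol.values >= level
    n_tv = int(tgt.sum())
    n_piv = int(piv.sum())
    n_tv_piv = int((tgt & piv).sum())
    if ci_definition == "paddick":
        ci = (n_tv_piv**2 / (n_tv * n_piv)) if n_piv else 0.0
    elif ci_definition == "rtog":
        ci = n_piv / n_tv
    else:
        raise ValueError(f"unknown CI definition {ci_definition!r}")

    vox_cc = structures[body_roi].voxel_volume_cc
    integral = float(vol.values[body].sum() * vox_cc)
    return {"HI": float(hi), "CI": float(ci), "ID_gy_cc": integral}


# ---------------------------------------------------------------------------
# NTCP


@dataclass
class NTCPModelParams:
    """Logistic NTCP model: endpoint, driving mean-dose metric, coefficients."""

    endpoint: str
    metric: str  # 'MHD' | 'MLD' | 'MED'
    intercept: float
    slope_per_gy: float
    #: optional clinical covariates: name -> per-unit coefficient
    covariate_coefs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in ("MHD", "MLD", "MED"):
            raise ValueError("metric must be MHD, MLD or MED")


def default_ntcp_models() -> dict[str, NTCPModelParams]:
    """Representative logistic models for the three lung-protocol endpoints.

    Coefficients are of the order found in published fits for these
    endpoints (per-Gy slopes of 0.05-0.13 on the driving mean dose); they
    are defaults for the synthetic pipeline, meant to be replaced by the
    coefficients of whichever national protocol applies.
    """
    return {
        "mortality_2y": NTCPModelParams(
            "2-year mortality", "MHD", intercept=-1.20, slope_per_gy=0.061,
            covariate_coefs={"age_over_65": 0.35},
        ),
        "pneumonitis_g2": NTCPModelParams(
            "pneumonitis grade >= 2", "MLD", intercept=-3.87, slope_per_gy=0.126,
            covariate_coefs={"pulmonary_comorbidity": 0.49},
        ),
        "dysphagia_g2": NTCPModelParams(
            "dysphagia grade >= 2", "MED", intercept=-2.77, slope_per_gy=0.067,
        ),
    }


def ntcp(params: NTCPModelParams, mean_dose_gy: float, covariates: dict[str, float] | None = None) -> float:
    """Logistic complication probability for one organ mean dose.

    Covariates listed in the model must be supplied (0/1 indicators or
    continuous values); extra covariates are rejected to catch typos.
    """
    covariates = covariates or {}
    missing = set(params.covariate_coefs) - set(covariates)
    if missing:
        raise ValueError(f"missing covariate(s): {sorted(missing)}")
    extra = set(covariates) - set(params.covariate_coefs)
    if extra:
        raise ValueError(f"unknown covariate(s): {sorted(extra)}")
    s = params.intercept + params.slope_per_gy * float(mean_dose_gy)
    for name, coef in params.covariate_coefs.items():
        s += coef * float(covariates[name])
    return float(1.0 / (1.0 + np.exp(-s)))


# ---------------------------------------------------------------------------
# paired statistical comparison


def compare_plans(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    *,
    label_a: str = "IMPT",
    label_b: str = "PAT",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired per-metric comparison of two plan cohorts (B minus A).

    Rows of each table are cohort members (same order), columns metrics.
    Reports the median of paired differences and the two-sided Wilcoxon
    signed-rank p (exact distribution for n <= 25, normal approximation
    above); differences are called non-significant when p exceeds
    ``alpha``.
    """
    if list(table_a.columns) != list(table_b.columns):
        raise ValueError("metric columns differ between cohorts")
    if len(table_a) != len(table_b):
        raise ValueError("cohorts must be paired (equal sizes)")
    n = len(table_a)
    if n < 5:
        warnings.warn("fewer than 5 pairs: the signed-rank test has little power")

    rows = []
    for col in table_a.columns:
        diff = table_b[col].to_numpy(dtype=float) - table_a[col].to_numpy(dtype=float)
        if np.allclose(diff, 0.0):
            warnings.warn(f"all paired differences are zero for {col!r}: degenerate test")
            p = 1.0
        else:
            method = "exact" if n <= 25 else "approx"
            try:
                p = float(wilcoxon(diff, zero_method="wilcox", method=method).pvalue)
            except ValueError:  # ties prevent the exact distribution
                p = float(wilcoxon(diff, zero_method="wilcox", method="approx").pvalue)
        rows.append(
            {
                "metric": col,
                f"median_{label_a}": float(np.median(table_a[col])),
                f"median_{label_b}": float(np.median(table_b[col])),
                "median_difference": float(np.median(diff)),
                "p_value": p,
                "significant": bool(p <= alpha),
            }
        )
    return pd.DataFrame(rows)
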