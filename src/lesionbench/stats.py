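"""Group statistics and the study's exclusion ledger.

Per-image mean metrics are screened with a 1.5×IQR fence, compared with
paired t-tests (Cohen's d on the paired differences), and probed with
Spearman correlations of lesion volume / histogram RMSE against accuracy.
The ledger tracks every set from simulation through parcellation to the
final analysis, so the arithmetic of exclusions is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "SetStatus",
    "StudyLedger",
    "iqr_outlier_screen",
    "paired_t",
    "spearman",
    "compile_ledger",
]

IMAGE_TYPES = ("lesion_free", "lesioned", "filled")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def iqr_outlier_screen(values, k: float = 1.5) -> np.ndarray:
    """Boolean flags for values beyond k×IQR from the quartiles.

    Quartiles use linear interpolation between order statistics (the common
    statistical-software default).  Requires at least 4 values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("outlier screen needs at least 4 values")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    d: float  # Cohen's d for paired data: mean(diff) / sd(diff)
    ci95: tuple[float, float]  # for the mean difference
    n: int
    mean_diff: float
    sd_diff: float


def paired_t(x, y) -> PairedTestResult:
    """Paired-samples t-test of x vs y with Cohen's d on the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t needs two equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("paired_t needs at least 3 pairs")
    diff = x - y
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero-variance differences: the paired t-test is degenerate")
    se = sd / math.sqrt(n)
    t = md / se
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    half = float(sps.t.ppf(0.975, df)) * se
    return PairedTestResult(
        t=t, df=df, p=p, d=md / sd, ci95=(md - half, md + half),
        n=n, mean_diff=md, sd_diff=sd,
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation: Pearson on average ranks, p via t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman needs two equal-length 1-D vectors")
    n = x.size
    if n < 4:
        raise ValueError("spearman needs at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman is undefined for a constant vector")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(abs(rho) - 1.0) < 1e-12:  # snap exact monotonicity to +/-1
        rho = math.copysign(1.0, rho)
    if abs(rho) >= 1.0:
        return math.copysign(1.0, rho), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# exclusion ledger
# ---------------------------------------------------------------------------

@dataclass
class SetStatus:
    """Per-set bookkeeping record: one (lesion-free, lesioned, filled) triple."""

    set_id: str
    tbi_id: str
    hc_id: str
    simulation_ok: bool
    # image_type -> {"attempts": int, "ok": bool}; empty when simulation failed
    parcellation: dict[str, dict] = field(default_factory=dict)
    outlier: bool = False

    @property
    def parcellation_ok(self) -> bool:
        if not self.simulation_ok:
            return False
        return all(
            self.parcellation.get(t, {}).get("ok", False) for t in IMAGE_TYPES
        )

    @property
    def included_in_group_stats(self) -> bool:
        return self.simulation_ok and self.parcellation_ok and not self.outlier


@dataclass
class StudyLedger:
    """Exclusion arithmetic over all simulated sets.

    Image counts mirror the study's reporting convention: each surviving set
    contributes its three images; the outlier screen operates at the metric
    stage, after parcellation, so the pre-outlier image count is three times
    the parcellation-surviving set count.
    """

    records: list[SetStatus]

    @property
    def n_sets_initial(self) -> int:
        return len(self.records)

    @property
    def sets_failed_simulation(self) -> list[str]:
        return [r.set_id for r in self.records if not r.simulation_ok]

    @property
    def sets_after_simulation(self) -> list[SetStatus]:
        return [r for r in self.records if r.simulation_ok]

    @property
    def sets_failed_parcellation(self) -> list[str]:
        return [r.set_id for r in self.sets_after_simulation if not r.parcellation_ok]

    @property
    def sets_after_parcellation(self) -> list[SetStatus]:
        return [r for r in self.sets_after_simulation if r.parcellation_ok]

    @property
    def outlier_sets(self) -> list[str]:
        return [r.set_id for r in self.sets_after_parcellation if r.outlier]

    @property
    def sets_included(self) -> list[SetStatus]:
        return [r for r in self.records if r.included_in_group_stats]

    def paired_test_df(self) -> int:
        """Degrees of freedom of the group paired tests (pairs − 1)."""
        return len(self.sets_included) - 1

    def counts(self) -> dict[str, int]:
        n_after_sim = len(self.sets_after_simulation)
        n_after_parc = len(self.sets_after_parcellation)
        report = {
            "n_sets_initial": self.n_sets_initial,
            "n_sets_failed_simulation": len(self.sets_failed_simulation),
            "n_sets_after_simulation": n_after_sim,
            "n_images_parcellated": 3 * n_after_sim,
            "n_sets_failed_parcellation": len(self.sets_failed_parcellation),
            "n_sets_after_parcellation": n_after_parc,
            "n_images_after_parcellation": 3 * n_after_parc,
            "n_outlier_sets": len(self.outlier_sets),
            "n_sets_included": len(self.sets_included),
            "paired_test_df": self.paired_test_df(),
        }
        # conservation: every initial set is included or excluded for a reason
        assert report["n_sets_initial"] == (
            report["n_sets_failed_simulation"]
            + report["n_sets_failed_parcellation"]
            + report["n_outlier_sets"]
            + report["n_sets_included"]
        )
        return report

    def to_dict(self) -> dict:
        return {
            "counts": self.counts(),
            "sets_failed_simulation": self.sets_failed_simulation,
            "sets_failed_parcellation": self.sets_failed_parcellation,
            "outlier_sets": self.outlier_sets,
            "sets_included": [r.set_id for r in self.sets_included],
            "records": [
                {
                    "set_id": r.set_id,
                    "tbi_id": r.tbi_id,
                    "hc_id": r.hc_id,
                    "simulation_ok": r.simulation_ok,
                    "parcellation": r.parcellation,
                    "outlier": r.outlier,
                    "included": r.included_in_group_stats,
                }
                for r in self.records
            ],
        }


def compile_ledger(records: list[SetStatus]) -> StudyLedger:
    """Assemble the exclusion ledger from per-set status records."""
    ledger = StudyLedger(records=list(records))
    ledger.counts()  # validates conservation
    return ledger
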