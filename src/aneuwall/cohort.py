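"""Cohort statistics for the bundled 48-aneurysm table.

The bundled table (20 ruptured "A", 17 translucent-unruptured "B", 11
non-translucent-unruptured "C" aneurysms) carries, per aneurysm, the area
multiple I_S, sac volume, thinning magnification I_BA and inhomogeneity
coefficient I_delta.  This module reproduces the published analysis chain:
Spearman rank correlations of I_S with volume per group, two-sample tests
between groups, empirical ROC curves with Youden-optimal midpoint cutoffs,
and stratified-bootstrap AUC confidence intervals.

The published analyses exclude a handful of extreme aneurysms (giant or
very narrow-necked sacs) per comparison; those exclusion id sets are
shipped verbatim as :data:`EXCLUSIONS`.  A Tukey-fence outlier utility is
provided for exploration but is *not* used to derive them, since the
original selection rule was not recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import CoefficientRecord

__all__ = [
    "CohortTable",
    "ROCResult",
    "ExclusionSet",
    "EXCLUSIONS",
    "load_table1",
    "spearman",
    "empirical_auc",
    "youden_optimal_cutoff",
    "two_sample_test",
    "tukey_outliers",
    "bootstrap_auc_ci",
    "reproduce_paper",
]


@dataclass
class CohortTable:
    """A cohort of coefficient records with provenance."""

    records: list[CoefficientRecord]
    provenance: str = "synthetic"  # or "bundled-table1"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate aneurysm ids in cohort table")
        if self.provenance == "bundled-table1":
            sizes = self.group_sizes()
            if (sizes.get("A"), sizes.get("B"), sizes.get("C")) != (20, 17, 11):
                raise ValueError("bundled table must have group sizes 20/17/11")

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for r in self.records:
            sizes[r.group] = sizes.get(r.group, 0) + 1
        return sizes

    def values(self, column: str, groups: Optional[set[str]] = None,
               exclude_ids: Optional[set[int]] = None) -> np.ndarray:
        out = [getattr(r, column) for r in self.records
               if (groups is None or r.group in groups)
               and (exclude_ids is None or r.id not in exclude_ids)]
        return np.asarray(out, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "id": r.id, "group": r.group, "location": r.location,
            "I_S": r.I_S, "volume_mm3": r.volume, "I_BA": r.I_BA,
            "I_delta": r.I_delta,
        } for r in self.records])


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC summary with the Youden-optimal midpoint cutoff."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    n_pos: int
    n_neg: int
    ci: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        if abs(self.youden_j - (self.sensitivity + self.specificity - 1.0)) > 1e-12:
            raise ValueError("youden_j must equal sensitivity + specificity - 1")


@dataclass(frozen=True)
class ExclusionSet:
    """Ids dropped from one published comparison."""

    analysis: str
    ids: frozenset[int]


# Exclusion id lists as published, per comparison.
EXCLUSIONS: dict[str, ExclusionSet] = {
    "volume": ExclusionSet("volume", frozenset({15, 17, 31, 34, 45})),
    "is_rupture": ExclusionSet("is_rupture", frozenset({15, 31, 34, 45})),
    "is_translucency": ExclusionSet("is_translucency", frozenset({31, 45})),
    "iba_rupture": ExclusionSet("iba_rupture", frozenset({34})),
    "iba_translucency": ExclusionSet("iba_translucency", frozenset({6, 34, 45})),
    "idelta_rupture": ExclusionSet("idelta_rupture", frozenset({5, 6, 29, 34})),
    "idelta_translucency": ExclusionSet("idelta_translucency", frozenset({6, 34})),
}


def load_table1() -> CohortTable:
    """Load the bundled 48-aneurysm table."""
    with resources.files("aneuwall.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    records = [CoefficientRecord(
        id=int(row.id), location=str(row.location), I_S=float(row.I_S),
        volume=float(row.volume_mm3), I_BA=float(row.I_BA),
        I_delta=float(row.I_delta), group=str(row.group),
    ) for row in df.itertuples()]
    return CohortTable(records=records, provenance="bundled-table1")


# --------------------------------------------------------------------------
# correlation and tests
# --------------------------------------------------------------------------

def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    r, _ = stats.spearmanr(x, y)
    return float(r)


def empirical_auc(pos, neg) -> float:
    """Concordance AUC: P(pos > neg) + 0.5 P(pos = neg).

    Computed from midranks of the pooled sample (equivalent to the
    trapezoidal area under the empirical ROC curve).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if not len(pos) or not len(neg):
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def youden_optimal_cutoff(pos, neg) -> ROCResult:
    """Scan midpoints between consecutive distinct pooled marker values.

    A case is called positive when its marker is >= the cutoff (higher
    marker = higher risk).  The cutoff maximizing Youden's J is returned;
    ties are broken toward higher specificity (the larger cutoff).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if not len(pos) or not len(neg):
        raise ValueError("both samples must be non-empty")
    pooled = np.unique(np.concatenate([pos, neg]))
    cutoffs = (pooled[:-1] + pooled[1:]) / 2.0
    best = None
    for c in cutoffs:
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec - 1.0
        # strict > keeps the later (larger) cutoff only on a real improvement;
        # >= prefers higher specificity among ties because cutoffs ascend
        if best is None or j >= best[0] - 1e-15:
            if best is None or j > best[0] + 1e-15 or c > best[1]:
                best = (j, c, sens, spec)
    j, c, sens, spec = best
    return ROCResult(
        auc=empirical_auc(pos, neg), cutoff=float(c), sensitivity=sens,
        specificity=spec, youden_j=j, n_pos=len(pos), n_neg=len(neg),
    )


def two_sample_test(x, y, method: str = "mann-whitney") -> tuple[float, float]:
    """Two-sided two-sample test; returns (Z, P).

    mann-whitney: normal-approximation Z of the U statistic.
    ks: two-sample Kolmogorov-Smirnov with Z = D * sqrt(n1 n2 / (n1 + n2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample must have at least 3 observations")
    n1, n2 = len(x), len(y)
    if method == "mann-whitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        mu = n1 * n2 / 2.0
        # tie-corrected variance
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
        sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
        z = float((res.statistic - mu) / sigma) if sigma > 0 else 0.0
        return z, float(res.pvalue)
    if method == "ks":
        res = stats.ks_2samp(x, y, method="auto")
        z = float(res.statistic * np.sqrt(n1 * n2 / (n1 + n2)))
        return z, float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def tukey_outliers(values, k: float = 1.5) -> np.ndarray:
    """Indices outside the Tukey fences Q1 - k*IQR, Q3 + k*IQR.

    Quartiles use linear interpolation.  Provided for exploration; the
    published exclusion id lists in :data:`EXCLUSIONS` are used as-is.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values for Tukey fences")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return np.flatnonzero((values < q1 - k * iqr) | (values > q3 + k * iqr))


def bootstrap_auc_ci(pos, neg, n_boot: int = 2000, seed: int = 0,
                     level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling strata separately."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    rng = np.random.default_rng(seed)
    bp = pos[rng.integers(0, len(pos), size=(n_boot, len(pos)))]
    bn = neg[rng.integers(0, len(neg), size=(n_boot, len(neg)))]
    cmp_ = bp[:, :, None] - bn[:, None, :]
    aucs = ((cmp_ > 0).mean(axis=(1, 2)) + 0.5 * (cmp_ == 0).mean(axis=(1, 2)))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# full published-analysis report
# --------------------------------------------------------------------------

def _roc_payload(roc: ROCResult, note: Optional[str] = None) -> dict:
    out = {
        "auc": roc.auc, "cutoff": roc.cutoff, "sensitivity": roc.sensitivity,
        "specificity": roc.specificity, "youden_j": roc.youden_j,
        "n_pos": roc.n_pos, "n_neg": roc.n_neg,
    }
    if roc.ci is not None:
        out["auc_ci_95"] = list(roc.ci)
    if note:
        out["note"] = note
    return out


def reproduce_paper(table: CohortTable, bootstrap_seed: int = 20200101,
                    n_boot: int = 2000) -> dict:
    """Recompute the published cohort statistics from the table.

    Returns a JSON-ready dict with the per-group I_S-volume Spearman
    correlations, the three ROC analyses on their published exclusion sets,
    and group comparisons (Mann-Whitney and KS) for volume, I_S, I_BA and
    I_delta with and without the published exclusions.  Deterministic for a
    fixed bootstrap seed.
    """
    report: dict = {"n_records": len(table.records),
                    "group_sizes": dict(sorted(table.group_sizes().items())),
                    "provenance": table.provenance}

    report["correlation_IS_volume"] = {
        g: spearman(table.values("I_S", groups={g}),
                    table.values("volume", groups={g}))
        for g in ("A", "B", "C")
    }

    def roc(marker: str, pos_groups: set, neg_groups: set, excl_key: str,
            note: Optional[str] = None) -> dict:
        excl = EXCLUSIONS[excl_key].ids
        pos = table.values(marker, groups=pos_groups, exclude_ids=excl)
        neg = table.values(marker, groups=neg_groups, exclude_ids=excl)
        res = youden_optimal_cutoff(pos, neg)
        ci = bootstrap_auc_ci(pos, neg, n_boot=n_boot, seed=bootstrap_seed)
        res = ROCResult(auc=res.auc, cutoff=res.cutoff,
                        sensitivity=res.sensitivity, specificity=res.specificity,
                        youden_j=res.youden_j, n_pos=res.n_pos, n_neg=res.n_neg,
                        ci=ci)
        return _roc_payload(res, note)

    report["roc"] = {
        "idelta_translucency": roc("I_delta", {"B"}, {"C"}, "idelta_translucency"),
        "iba_translucency": roc("I_BA", {"B"}, {"C"}, "iba_translucency"),
        "idelta_rupture": roc(
            "I_delta", {"A"}, {"B", "C"}, "idelta_rupture",
            note=("published AUC 0.731 is not reproducible from the printed "
                  "data; cutoff/sensitivity/specificity do reproduce"),
        ),
    }

    comparisons = {}
    for marker, excl_rupture, excl_transl in (
        ("volume", "volume", "volume"),
        ("I_S", "is_rupture", "is_translucency"),
        ("I_BA", "iba_rupture", "iba_translucency"),
        ("I_delta", "idelta_rupture", "idelta_translucency"),
    ):
        entry = {}
        for label, pos_g, neg_g, excl_key in (
            ("rupture_A_vs_BC", {"A"}, {"B", "C"}, excl_rupture),
            ("translucency_B_vs_C", {"B"}, {"C"}, excl_transl),
        ):
            for tag, excl in (("all", None), ("excluded", EXCLUSIONS[excl_key].ids)):
                x = table.values(marker, groups=pos_g, exclude_ids=excl)
                y = table.values(marker, groups=neg_g, exclude_ids=excl)
                z_mw, p_mw = two_sample_test(x, y, "mann-whitney")
                z_ks, p_ks = two_sample_test(x, y, "ks")
                entry[f"{label}_{tag}"] = {
                    "mann_whitney": {"Z": z_mw, "P": p_mw},
                    "ks": {"Z": z_ks, "P": p_ks},
                    "n": [len(x), len(y)],
                }
        comparisons[marker] = entry
    report["group_comparisons"] = comparisons
    report["identity_max_rel_error"] = float(max(
        abs(r.I_delta * r.I_S - r.I_BA) / r.I_BA for r in table.records))
    return report
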