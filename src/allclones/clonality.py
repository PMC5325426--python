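"""Mutation-burden comparison, AF-based clonality and substitution spectra.

At diagnosis a mutation present in the founding leukemic clone is expected
at an allele fraction near blast_fraction / 2 (near blast_fraction for
hemizygous chrX-in-male and mitochondrial sites), while subclonal mutations
sit lower; cohort-wide the AF distribution is bimodal, and the valley
between the two density modes separates clonal from subclonal calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BoundaryEstimate",
    "estimate_af_boundary",
    "ploidy_factor",
    "classify_clonality",
    "compare_burden",
    "clonal_fraction_test",
    "substitution_spectrum",
    "burden_age_correlation",
]

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class BoundaryEstimate:
    """Valley between the clonal and subclonal AF density modes.

    ``boundary`` is None when the smoothed density is unimodal on the search
    interval (an explicit "no boundary" result, not an error).
    """

    boundary: float | None
    method: str
    grid: np.ndarray
    density: np.ndarray
    modes: tuple | None = None

    @property
    def found(self) -> bool:
        return self.boundary is not None


def estimate_af_boundary(
    afs: Sequence[float],
    grid_range: tuple[float, float] = (0.05, 0.5),
    grid_points: int = 400,
) -> BoundaryEstimate:
    """Locate the density valley separating the two AF peaks.

    A Gaussian kernel density (Silverman bandwidth) is evaluated on a fixed
    grid; the boundary is the argmin between the two largest local maxima.
    Hemizygous sites must be pre-scaled by their ploidy factor.
    Requires at least 50 AF values in (0, 1).
    """
    afs = np.asarray([a for a in afs if a is not None and not np.isnan(a)], dtype=float)
    afs = afs[(afs > 0) & (afs < 1)]
    if len(afs) < 50:
        raise ValueError(f"need >= 50 AF values in (0,1), got {len(afs)}")

    kde = stats.gaussian_kde(afs, bw_method="silverman")
    grid = np.linspace(grid_range[0], grid_range[1], grid_points)
    density = kde(grid)

    interior = np.arange(1, grid_points - 1)
    is_max = (density[interior] >= density[interior - 1]) & (
        density[interior] >= density[interior + 1]
    )
    mode_idx = interior[is_max]
    # merge flat plateaus
    mode_idx = mode_idx[np.concatenate(([True], np.diff(mode_idx) > 1))]
    # allow a mode at the right edge (clonal peak can sit near 0.5)
    if density[-1] > density[-2]:
        mode_idx = np.append(mode_idx, grid_points - 1)
    if density[0] > density[1]:
        mode_idx = np.append(0, mode_idx)

    if len(mode_idx) < 2:
        return BoundaryEstimate(None, "kde_valley", grid, density, None)

    top_two = mode_idx[np.argsort(density[mode_idx])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    valley = lo + int(np.argmin(density[lo : hi + 1]))
    return BoundaryEstimate(
        boundary=float(grid[valley]),
        method="kde_valley",
        grid=grid,
        density=density,
        modes=(float(grid[lo]), float(grid[hi])),
    )


def ploidy_factor(chrom: str, sex: str) -> float:
    """2 for chrX in males and mitochondrial sites, else 1."""
    c = str(chrom).removeprefix("chr")
    if c == "X" and sex == "M":
        return 2.0
    if c in ("M", "MT"):
        return 2.0
    return 1.0


def classify_clonality(
    mutations: pd.DataFrame,
    boundary: float,
    sex_by_patient: Mapping[str, str],
    exclude_hemizygous: bool = False,
) -> pd.DataFrame:
    """Label each mutation clonal/subclonal by its ploidy-adjusted AF.

    ``mutations`` needs patient_id, chrom, pos, ref, alt, af.  Rows with
    missing AF are skipped (counted in the ``skipped_missing_af`` attr).
    The hemizygous adjustment divides AF by 2 rather than dropping the
    records; ``exclude_hemizygous=True`` drops them instead.
    """
    rows = []
    skipped = 0
    for r in mutations.itertuples(index=False):
        af = getattr(r, "af", None)
        if af is None or (isinstance(af, float) and np.isnan(af)):
            skipped += 1
            continue
        pf = ploidy_factor(str(r.chrom), sex_by_patient.get(str(r.patient_id), "F"))
        if exclude_hemizygous and pf == 2.0:
            continue
        adjusted = float(af) / pf
        rows.append(
            {
                "patient_id": r.patient_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "af": float(af),
                "ploidy_factor": pf,
                "adjusted_af": adjusted,
                "label": "clonal" if adjusted >= boundary else "subclonal",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["patient_id", "chrom", "pos", "ref", "alt", "af",
                 "ploidy_factor", "adjusted_af", "label"],
    )
    out.attrs["skipped_missing_af"] = skipped
    return out


def compare_burden(
    groups: Mapping[str, Sequence[float]], test: str = "wilcoxon"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of per-patient burdens.

    Exact null distribution when both groups have n <= 12 and no ties;
    normal approximation with mid-rank tie correction otherwise.
    """
    if test != "wilcoxon":
        raise ValueError(f"unsupported test: {test!r}")
    if len(groups) != 2:
        raise ValueError("compare_burden takes exactly two groups")
    (na, a), (nb, b) = ((k, np.asarray(v, float)) for k, v in groups.items())
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 12 and len(b) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def clonal_fraction_test(
    table: Sequence[Sequence[float]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) on a 2x2 clonal/subclonal x group table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("cell counts must be >= 0")
    if (arr.sum(axis=0) <= 0).any() or (arr.sum(axis=1) <= 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


def _collapse_substitution(ref: str, alt: str) -> str:
    ref, alt = ref.upper(), alt.upper()
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    sub = f"{ref}>{alt}"
    if sub not in SPECTRUM_CLASSES:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return sub


def substitution_spectrum(
    snvs: pd.DataFrame, group_by: str | None = None
) -> pd.DataFrame:
    """Six-class substitution fractions (pyrimidine-reference collapse).

    ``snvs`` must contain SNVs only (single-base ref/alt); non-SNV rows are
    an error.  With ``group_by`` set, one row of fractions per group value,
    each summing to 1.
    """
    if len(snvs) == 0:
        raise ValueError("no SNVs supplied")
    for r in snvs.itertuples(index=False):
        if len(str(r.ref)) != 1 or len(str(r.alt)) != 1:
            raise ValueError(f"non-SNV record at {r.chrom}:{r.pos}")
    subs = [
        _collapse_substitution(str(r.ref), str(r.alt))
        for r in snvs.itertuples(index=False)
    ]
    frame = pd.DataFrame({"substitution": subs})
    if group_by is None:
        frame["group"] = "all"
    else:
        frame["group"] = snvs[group_by].to_numpy()
    counts = (
        frame.groupby("group")["substitution"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=SPECTRUM_CLASSES, fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def burden_age_correlation(
    counts: Sequence[float], ages: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between mutation counts and age."""
    counts = np.asarray(counts, float)
    ages = np.asarray(ages, float)
    if len(counts) != len(ages):
        raise ValueError("paired vectors required")
    if len(counts) < 5:
        raise ValueError("need n >= 5 pairs")
    if np.ptp(counts) == 0 or np.ptp(ages) == 0:
        raise ValueError("constant vector has no rank correlation")
    rho, p = stats.spearmanr(counts, ages)
    return float(rho), float(p)
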