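"""Driver-gene discovery: burden excess, impact bias, positional clustering.

Three per-subgroup statistics capture the three classic driver axes — more
mutations than expected from the background rate, a shift toward
high-functional-impact mutations, and tight positional clustering.  They
are deliberately simplified, dependency-free analogues of the heavyweight
tools used for cohort-scale screens (which rely on external covariate and
score files), not re-implementations of them.  Per-subgroup q-values come
from Benjamini-Hochberg; the consensus rule calls a gene a putative driver
when it is predicted in at least one patient subgroup and carries at least
three non-silent mutations cohort-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import NON_SILENT_EFFECTS

__all__ = [
    "DEFAULT_SUBGROUPS",
    "RAS_GENES",
    "burden_test",
    "impact_bias_test",
    "clustering_test",
    "estimate_background_rate",
    "bh_qvalues",
    "driver_screen",
    "consensus_drivers",
    "ConsensusDriver",
    "driver_summary",
]

#: The five discovery subsets: T immunophenotype, all B-cell-precursor
#: patients, and the three largest BCP subtypes.
DEFAULT_SUBGROUPS = ("T-ALL", "BCP-ALL", "HeH", "t(12;21)", "normal")

RAS_GENES = frozenset({"KRAS", "NRAS", "PTPN11", "FLT3"})


def burden_test(
    coding_length_bp: int,
    observed_nonsilent: int,
    background_rate_per_bp: float,
    n_patients: int,
) -> float:
    """Upper-tail Poisson p for an excess of non-silent mutations.

    Expected count = background rate/bp/patient x coding length x patients.
    """
    if coding_length_bp <= 0:
        raise ValueError("coding length must be > 0")
    if background_rate_per_bp <= 0:
        raise ValueError("background rate must be > 0")
    mean = background_rate_per_bp * coding_length_bp * n_patients
    return float(stats.poisson.sf(observed_nonsilent - 1, mean))


def impact_bias_test(
    gene_scores: Sequence[float],
    cohort_scores: Sequence[float],
    n_perm: int = 2000,
    seed: int = 0,
) -> float | None:
    """One-sided rank-sum p for gene impact scores exceeding background.

    The null distribution of the mid-rank sum is evaluated by permutation
    (random subsets of the pooled scores), which stays valid under the
    heavy ties of discrete effect-severity scores, where the normal
    approximation is badly anticonservative.  Returns None (not tested)
    for genes with fewer than two scored mutations; a fully tied
    comparison yields p = 1 under the mid-rank convention.
    """
    gene_scores = np.asarray(gene_scores, float)
    cohort_scores = np.asarray(cohort_scores, float)
    if len(gene_scores) < 2:
        return None
    pooled = np.concatenate([gene_scores, cohort_scores])
    if np.ptp(pooled) == 0:
        return 1.0
    ranks = stats.rankdata(pooled)
    n_g = len(gene_scores)
    observed = ranks[:n_g].sum()
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)[:, :n_g]
    null = ranks[idx].sum(axis=1)
    return float((1 + (null >= observed - 1e-9).sum()) / (n_perm + 1))


def _max_window_fraction(positions: np.ndarray, window: int) -> float:
    positions = np.sort(positions)
    # rightmost index with position <= p_i + window - 1
    upper = np.searchsorted(positions, positions + window - 1, side="right")
    return float(np.max(upper - np.arange(len(positions))) / len(positions))


def clustering_test(
    positions_in_cds: Sequence[int],
    cds_length: int,
    window: int = 30,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for positional clustering of mutations in a CDS.

    Statistic: max over sliding windows of the fraction of mutations inside.
    Null: positions uniform on the CDS; p has +1 smoothing, so
    p >= 1/(n_perm+1) always.
    """
    positions = np.asarray(positions_in_cds, dtype=int)
    if len(positions) < 3:
        raise ValueError("need >= 3 positions")
    if window > cds_length:
        raise ValueError("window exceeds CDS length")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = _max_window_fraction(positions, window)
    rng = np.random.default_rng(seed)
    null = rng.integers(1, cds_length + 1, size=(n_perm, len(positions)))
    null.sort(axis=1)
    upper = np.empty_like(null)
    for i in range(n_perm):  # searchsorted per draw; n_perm x n log n
        upper[i] = np.searchsorted(null[i], null[i] + window - 1, side="right")
    exceed = (
        (upper - np.arange(len(positions))[np.newaxis, :]).max(axis=1) / len(positions)
    ) >= observed - 1e-12
    return float((1 + exceed.sum()) / (n_perm + 1))


def estimate_background_rate(
    mutations: pd.DataFrame,
    total_coding_length_bp: float,
    n_patients: int,
) -> float:
    """Cohort-wide per-bp per-patient non-silent background rate.

    The neutral mutation rate is anchored on silent + noncoding calls and
    scaled by the cohort's non-silent/neutral ratio to put it on the
    non-silent scale used by :func:`burden_test`.
    """
    neutral = int((~mutations["effect"].isin(NON_SILENT_EFFECTS)).sum())
    non_silent = int(mutations["effect"].isin(NON_SILENT_EFFECTS).sum())
    if neutral == 0:
        raise ValueError("no silent/noncoding mutations to anchor the background")
    neutral_rate = neutral / (total_coding_length_bp * n_patients)
    return neutral_rate * (non_silent / neutral)


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def driver_screen(
    mutations: pd.DataFrame,
    patients: pd.DataFrame,
    gene_models: pd.DataFrame,
    subgroups: Sequence[str] = DEFAULT_SUBGROUPS,
    impact_scores: Mapping[str, float] | None = None,
    window: int = 30,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene, per-subgroup driver statistics on diagnostic mutations.

    Returns a tidy frame (gene, subgroup, statistic, p).  The burden test
    runs for every mutated gene; the impact test uses ``impact_scores``
    (0-1 per effect class; a built-in severity map by default); the
    clustering test runs for genes with >= 3 mutations in the subgroup.
    """
    if impact_scores is None:
        impact_scores = {
            "nsSNV": 0.6, "nonsense": 1.0, "frameshift": 1.0,
            "nonframeshift_indel": 0.7, "splice": 0.9,
            "silent": 0.0, "noncoding": 0.0,
        }
    gene_len = dict(zip(gene_models["gene"], gene_models["coding_length_bp"]))
    gene_start = (
        dict(zip(gene_models["gene"], gene_models["start"]))
        if "start" in gene_models.columns
        else {}
    )
    dia = mutations[(mutations["timepoint"] == "diagnosis") & mutations["called"]]

    rows = []
    for subgroup in subgroups:
        if subgroup == "BCP-ALL":
            pids = set(patients.loc[patients["immunophenotype"] == "BCP", "patient_id"])
        else:
            pids = set(patients.loc[patients["subtype"] == subgroup, "patient_id"])
        sub = dia[dia["patient_id"].isin(pids)]
        if sub.empty:
            continue
        n_pat = len(pids)
        ns = sub[sub["effect"].isin(NON_SILENT_EFFECTS) & sub["gene"].notna()]
        total_len = float(sum(gene_len.values()))
        try:
            rate = estimate_background_rate(sub, total_len, n_pat)
        except ValueError:
            rate = 1.0 / (total_len * n_pat)  # floor when no neutral calls
        all_scores = ns["effect"].map(impact_scores).astype(float)

        for gi, (gene, gmut) in enumerate(ns.groupby("gene")):
            cohort_scores = all_scores[ns["gene"] != gene].to_numpy()
            length = gene_len.get(gene)
            if length is None:
                continue
            p_burden = burden_test(int(length), len(gmut), rate, n_pat)
            rows.append(
                {"gene": gene, "subgroup": subgroup, "statistic": "burden",
                 "p": p_burden, "n_non_silent": len(gmut)}
            )
            p_imp = impact_bias_test(
                gmut["effect"].map(impact_scores).to_numpy(float),
                cohort_scores,
                seed=seed + 31 * gi,
            )
            if p_imp is not None:
                rows.append(
                    {"gene": gene, "subgroup": subgroup, "statistic": "impact_bias",
                     "p": p_imp, "n_non_silent": len(gmut)}
                )
            if len(gmut) >= 3 and gene in gene_start:
                cds_pos = (gmut["pos"].to_numpy(int) - int(gene_start[gene])) % int(
                    length
                ) + 1
                p_clu = clustering_test(
                    cds_pos, int(length), window=window, n_perm=n_perm,
                    seed=seed + gi,
                )
                rows.append(
                    {"gene": gene, "subgroup": subgroup, "statistic": "clustering",
                     "p": p_clu, "n_non_silent": len(gmut)}
                )
    return pd.DataFrame(
        rows, columns=["gene", "subgroup", "statistic", "p", "n_non_silent"]
    )


@dataclass
class ConsensusDriver:
    gene: str
    supporting_subgroups: tuple
    n_non_silent: int
    is_driver: bool


def consensus_drivers(
    calls: pd.DataFrame,
    mutations: pd.DataFrame,
    q_threshold: float = 0.1,
    require_all_statistics: bool = False,
) -> list[ConsensusDriver]:
    """Apply BH within each (subgroup, statistic) family and the consensus rule.

    A gene is a putative driver iff it is predicted (any statistic at
    q <= threshold, or all statistics when ``require_all_statistics``) in at
    least one subgroup AND harbors at least three non-silent mutations in
    the diagnostic cohort.
    """
    calls = calls.copy()
    calls["q"] = np.nan
    for (_, _), idx in calls.groupby(["subgroup", "statistic"]).groups.items():
        calls.loc[idx, "q"] = bh_qvalues(calls.loc[idx, "p"].to_numpy())

    dia = mutations[(mutations["timepoint"] == "diagnosis") & mutations["called"]]
    ns_counts = (
        dia[dia["effect"].isin(NON_SILENT_EFFECTS)]
        .groupby("gene")
        .size()
        .to_dict()
    )

    out = []
    for gene, gcalls in calls.groupby("gene"):
        supporting = []
        for subgroup, sub in gcalls.groupby("subgroup"):
            hits = sub["q"] <= q_threshold
            predicted = bool(hits.all()) if require_all_statistics else bool(hits.any())
            if predicted:
                supporting.append(subgroup)
        n_ns = int(ns_counts.get(gene, 0))
        out.append(
            ConsensusDriver(
                gene=gene,
                supporting_subgroups=tuple(sorted(supporting)),
                n_non_silent=n_ns,
                is_driver=bool(supporting) and n_ns >= 3,
            )
        )
    return sorted(out, key=lambda d: d.gene)


def _round_half_up_pct(numerator: float, denominator: float) -> int:
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(np.floor(100.0 * numerator / denominator + 0.5))


def driver_summary(
    driver_genes: Sequence[str],
    mutations: pd.DataFrame,
    patients: pd.DataFrame,
    ras_genes: frozenset | set = RAS_GENES,
) -> pd.DataFrame:
    """Per-subtype cohort summary over a resolved driver-gene list.

    Columns: n_patients, n_ras_mutated (+pct), mean non-silent driver
    mutations per patient, n_no_driver (+pct).  Percentages are rounded
    half-up to integers.  A trailing "all" row covers the whole cohort.
    """
    from .io import SUBTYPES

    unknown = set(patients["subtype"]) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"unknown subtype label(s): {sorted(unknown)}")

    driver_genes = set(driver_genes)
    dia = mutations[
        (mutations["timepoint"] == "diagnosis")
        & mutations["called"]
        & mutations["effect"].isin(NON_SILENT_EFFECTS)
    ]
    ras_patients = set(dia.loc[dia["gene"].isin(ras_genes), "patient_id"])
    driver_counts = (
        dia[dia["gene"].isin(driver_genes)].groupby("patient_id").size().to_dict()
    )

    def row(label: str, pids: list[str]) -> dict:
        n = len(pids)
        n_ras = sum(p in ras_patients for p in pids)
        counts = [driver_counts.get(p, 0) for p in pids]
        n_none = sum(c == 0 for c in counts)
        return {
            "subtype": label,
            "n_patients": n,
            "n_ras_mutated": n_ras,
            "pct_ras_mutated": _round_half_up_pct(n_ras, n),
            "mean_driver_mutations": float(np.mean(counts)) if counts else 0.0,
            "n_no_driver": n_none,
            "pct_no_driver": _round_half_up_pct(n_none, n),
        }

    rows = []
    for subtype, sub in patients.groupby("subtype", sort=False):
        rows.append(row(str(subtype), list(sub["patient_id"])))
    rows.append(row("all", list(patients["patient_id"])))
    return pd.DataFrame(rows).set_index("subtype")
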