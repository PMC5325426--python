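"""Competing-risks relapse analysis: cumulative incidence and Gray's test.

Relapse competes with death in first remission, secondary malignancy and
resistant disease: the probability of relapse by time t is therefore the
Aalen-Johansen cumulative incidence, not one minus Kaplan-Meier survival.
Group comparisons use Gray's K-sample test on the subdistribution hazard of
the event of interest.  The score is computed with the standard
inverse-probability-of-censoring weighting (pooled censoring Kaplan-Meier):
a subject who fails from a competing cause stays in the weighted risk set
with weight G(t-)/G(T_i).  P-values come either from a chi-square reference
with a plug-in (log-rank style) variance, or - the package default - from a
permutation null, which is exact under exchangeable group labels; an
exhaustive enumeration is used automatically when it is cheap.

The gene/pathway relapse screen applies the study-style filters: non-silent
mutations only, infants excluded, and only units mutated in at least five
patients of the analyzed subgroup, with Bonferroni correction over the
units actually tested in that subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import NON_SILENT_EFFECTS

__all__ = [
    "COMPETING_EVENTS",
    "CIFEstimate",
    "GrayResult",
    "survival_records",
    "cumulative_incidence",
    "gray_test",
    "pathway_collapse",
    "relapse_screen",
]

#: Outcomes treated as competing events for relapse.
COMPETING_EVENTS = ("DCR1", "SMN", "resistant")


@dataclass
class CIFEstimate:
    """Aalen-Johansen cumulative incidence for one event type."""

    event: str
    times: np.ndarray
    cif: np.ndarray
    n_at_risk: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cif[idx])


@dataclass
class GrayResult:
    statistic: float
    df: int
    p: float
    method: str
    m: int = 1

    @property
    def bonferroni_p(self) -> float:
        return min(1.0, self.p * self.m)


def survival_records(patients: pd.DataFrame) -> pd.DataFrame:
    """Patient metadata → survival table (patient_id, time, event).

    CR1 maps to censored; DCR1/SMN/resistant are competing events.
    """
    events = patients["outcome"].map(
        lambda o: "censored" if o == "CR1" else (
            "relapse" if o == "relapse" else "competing"
        )
    )
    out = pd.DataFrame(
        {
            "patient_id": patients["patient_id"],
            "time": patients["time_to_event_years"].astype(float),
            "event": events,
        }
    )
    if (out["time"] <= 0).any():
        raise ValueError("non-positive follow-up time")
    return out.reset_index(drop=True)


def _status_codes(events: pd.Series, event_of_interest: str) -> np.ndarray:
    """0 censored, 1 event of interest, 2 competing."""
    return np.where(
        events == event_of_interest, 1, np.where(events == "censored", 0, 2)
    )


def cumulative_incidence(
    records: pd.DataFrame, event_of_interest: str = "relapse"
) -> CIFEstimate:
    """Aalen-Johansen CIF: increments are S(t-) x cause-specific hazard.

    Ties are resolved events-before-censorings: subjects censored at t are
    still at risk for events at t.
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    time = records["time"].to_numpy(float)
    if (time <= 0).any():
        raise ValueError("non-positive follow-up time")
    status = _status_codes(records["event"], event_of_interest)

    times = np.unique(time[status > 0])
    cif_vals, n_risk = [], []
    surv = 1.0
    cif = 0.0
    for t in times:
        at_risk = int((time >= t).sum())
        d_int = int(((time == t) & (status == 1)).sum())
        d_all = int(((time == t) & (status > 0)).sum())
        cif += surv * d_int / at_risk
        surv *= 1.0 - d_all / at_risk
        cif_vals.append(cif)
        n_risk.append(at_risk)
    return CIFEstimate(
        event=event_of_interest,
        times=times,
        cif=np.asarray(cif_vals),
        n_at_risk=np.asarray(n_risk, dtype=int),
    )


# ---------------------------------------------------------------------------
# Gray's K-sample test
# ---------------------------------------------------------------------------

def _censoring_km(time: np.ndarray, status: np.ndarray):
    """Pooled censoring Kaplan-Meier; returns step times and G values.

    Events precede censorings at tied times, so the at-risk set for a
    censoring at t excludes subjects failing at t.
    """
    times = np.unique(time)
    g_vals = []
    g = 1.0
    for t in times:
        at_risk = int((time >= t).sum())
        d_all = int(((time == t) & (status > 0)).sum())
        c = int(((time == t) & (status == 0)).sum())
        denom = at_risk - d_all
        if denom > 0 and c > 0:
            g *= 1.0 - c / denom
        g_vals.append(g)
    return times, np.asarray(g_vals)


def _g_lookup(step_times, g_vals, t, left=False):
    side = "left" if left else "right"
    idx = np.searchsorted(step_times, t, side=side) - 1
    return np.where(idx < 0, 1.0, g_vals[np.clip(idx, 0, len(g_vals) - 1)])


def _score_ingredients(time: np.ndarray, status: np.ndarray, rho: float):
    """Weighted risk-set matrix W and cause-1 event matrix D (times x n)."""
    tau = np.unique(time[status == 1])
    if len(tau) == 0:
        raise ValueError("no events of interest (all censored or competing)")
    n = len(time)
    gs_t, gs_v = _censoring_km(time, status)
    g_left_tau = _g_lookup(gs_t, gs_v, tau, left=True)  # G(tau-)
    g_at_subj = _g_lookup(gs_t, gs_v, time, left=False)  # G(T_i)

    at_risk = time[np.newaxis, :] >= tau[:, np.newaxis]
    competing_prior = (time[np.newaxis, :] < tau[:, np.newaxis]) & (
        status[np.newaxis, :] == 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ipcw = np.where(
            g_at_subj[np.newaxis, :] > 0,
            g_left_tau[:, np.newaxis] / g_at_subj[np.newaxis, :],
            0.0,
        )
    W = at_risk.astype(float) + competing_prior * ipcw
    D = ((time[np.newaxis, :] == tau[:, np.newaxis]) & (status == 1)).astype(float)

    if rho != 0:
        # pooled CIF for the rho-family weight (1 - F1(t-))^rho
        pooled = cumulative_incidence(
            pd.DataFrame({"time": time, "event": np.where(
                status == 1, "relapse", np.where(status == 0, "censored", "competing")
            )}),
            "relapse",
        )
        f1_left = np.array([pooled.at(t - 1e-12) for t in tau])
        wrho = (1.0 - f1_left) ** rho
    else:
        wrho = np.ones(len(tau))
    return W, D, wrho


def _scores_and_stat(W, D, wrho, membership):
    """Score vector z (K-1 groups) and naive chi-square statistic."""
    R = W.sum(axis=1)
    d1 = D.sum(axis=1)
    K = membership.shape[1]
    z = np.empty(K)
    for k in range(K):
        u = membership[:, k]
        Rk = W @ u
        dk = D @ u
        z[k] = float((wrho * (dk - Rk * d1 / R)).sum())
    V = np.zeros((K, K))
    for k in range(K):
        for l in range(K):
            pk = (W @ membership[:, k]) / R
            pl = (W @ membership[:, l]) / R
            delta = 1.0 if k == l else 0.0
            V[k, l] = float((wrho**2 * d1 * pk * (delta - pl)).sum())
    zr, Vr = z[:-1], V[:-1, :-1]
    if np.allclose(zr, 0.0):
        return z, 0.0
    stat = float(zr @ np.linalg.pinv(Vr) @ zr)
    return z, max(stat, 0.0)


def _stat_two_group_batch(W, D, wrho, U):
    """Chi-square-style statistic for many 0/1 membership columns at once."""
    R = W.sum(axis=1)[:, np.newaxis]
    d1 = D.sum(axis=1)[:, np.newaxis]
    RA = W @ U
    dA = D @ U
    z = (wrho[:, np.newaxis] * (dA - RA * d1 / R)).sum(axis=0)
    pA = RA / R
    V = (wrho[:, np.newaxis] ** 2 * d1 * pA * (1.0 - pA)).sum(axis=0)
    stat = np.where(V > 0, z**2 / np.where(V > 0, V, 1.0), 0.0)
    return stat


def gray_test(
    records: pd.DataFrame,
    groups: Sequence | pd.Series | None = None,
    event_of_interest: str = "relapse",
    rho: float = 0.0,
    method: str = "permutation",
    n_perm: int = 2000,
    exhaustive_limit: int = 20000,
    seed: int = 0,
) -> GrayResult:
    """Gray's K-sample test for equal cumulative incidence of one event.

    ``records`` has columns time and event (plus optional group); ``groups``
    supplies the group label per row otherwise.  ``method`` is
    "permutation" (default; switches to exhaustive enumeration for two
    groups when the number of assignments is within ``exhaustive_limit``)
    or "asymptotic" (chi-square, K-1 df, plug-in variance).
    """
    time = records["time"].to_numpy(float)
    status = _status_codes(records["event"], event_of_interest)
    labels = np.asarray(records["group"] if groups is None else groups)
    if len(labels) != len(time):
        raise ValueError("group labels must match records")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 non-empty groups")
    for g in uniq:
        if (labels == g).sum() == 0:
            raise ValueError(f"empty group {g!r}")
    if (status == 1).sum() == 0:
        raise ValueError("no events of interest in the data")

    W, D, wrho = _score_ingredients(time, status, rho)
    membership = np.stack([(labels == g).astype(float) for g in uniq], axis=1)
    _, observed = _scores_and_stat(W, D, wrho, membership)
    df = len(uniq) - 1

    if method == "asymptotic":
        p = float(stats.chi2.sf(observed, df)) if observed > 0 else 1.0
        return GrayResult(observed, df, p, "asymptotic")
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    n = len(time)
    if len(uniq) == 2:
        nA = int((labels == uniq[0]).sum())
        total = comb(n, nA)
        if total <= exhaustive_limit:
            U = np.zeros((n, total))
            for j, idx in enumerate(combinations(range(n), nA)):
                U[list(idx), j] = 1.0
            stats_all = _stat_two_group_batch(W, D, wrho, U)
            p = float((stats_all >= observed - 1e-12).mean())
            return GrayResult(observed, df, p, "exhaustive")
        rng = np.random.default_rng(seed)
        base = (labels == uniq[0]).astype(float)
        U = np.empty((n, n_perm))
        for j in range(n_perm):
            U[:, j] = base[rng.permutation(n)]
        stats_all = _stat_two_group_batch(W, D, wrho, U)
        p = float((1 + (stats_all >= observed - 1e-12).sum()) / (n_perm + 1))
        return GrayResult(observed, df, p, "permutation")

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, s = _scores_and_stat(W, D, wrho, membership[perm])
        if s >= observed - 1e-12:
            exceed += 1
    p = float((1 + exceed) / (n_perm + 1))
    return GrayResult(observed, df, p, "permutation")


# ---------------------------------------------------------------------------
# Gene / pathway relapse screen
# ---------------------------------------------------------------------------

def pathway_collapse(
    mutations: pd.DataFrame, pathway_map: pd.DataFrame
) -> pd.DataFrame:
    """Per-patient per-pathway mutated flags from non-silent mutations.

    A patient is mutated in a pathway iff they carry at least one non-silent
    mutation in any member gene.  Genes missing from the map are ignored
    (their count is available as the frame's ``unmapped_genes`` attr).
    """
    ns = mutations[
        mutations["effect"].isin(NON_SILENT_EFFECTS) & mutations["gene"].notna()
    ]
    mapped = ns.merge(pathway_map[["gene", "pathway_id"]], on="gene", how="left")
    unmapped = int(mapped["pathway_id"].isna().groupby(mapped["gene"]).any().sum())
    mapped = mapped.dropna(subset=["pathway_id"])
    flags = (
        mapped.groupby(["patient_id", "pathway_id"]).size().gt(0).unstack(
            fill_value=False
        )
    )
    flags.attrs["unmapped_genes"] = unmapped
    return flags


def _subgroup_patients(patients: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    if subgroup == "all":
        return patients
    if subgroup == "T-ALL":
        return patients[patients["immunophenotype"] == "T"]
    if subgroup == "BCP-ALL":
        return patients[patients["immunophenotype"] == "BCP"]
    if subgroup.startswith("BCP-ALL:risk="):
        if "risk_group" not in patients.columns:
            raise ValueError("risk-stratified subgroup needs a risk_group column")
        risk = subgroup.split("=", 1)[1]
        return patients[
            (patients["immunophenotype"] == "BCP") & (patients["risk_group"] == risk)
        ]
    return patients[patients["subtype"] == subgroup]


def relapse_screen(
    mutations: pd.DataFrame,
    patients: pd.DataFrame,
    unit: str = "gene",
    pathway_map: pd.DataFrame | None = None,
    subgroup: str = "BCP-ALL",
    min_mutated: int = 5,
    min_age_years: float = 1.0,
    gray_kwargs: Mapping | None = None,
) -> pd.DataFrame:
    """Screen genes or pathways for association with relapse.

    Within the analyzed subgroup (infants below ``min_age_years`` removed
    first), every unit with non-silent mutations in at least ``min_mutated``
    patients is tested mutated-vs-unmutated with Gray's test; Bonferroni m
    is the number of units actually tested in this subgroup.
    """
    if unit not in ("gene", "pathway"):
        raise ValueError("unit must be gene or pathway")
    if unit == "pathway" and pathway_map is None:
        raise ValueError("pathway screen needs a pathway map")

    cohort = _subgroup_patients(patients, subgroup)
    cohort = cohort[cohort["age_years"] >= min_age_years]
    if cohort.empty:
        raise ValueError(f"no patients left in subgroup {subgroup!r} after filters")
    surv = survival_records(cohort).set_index(cohort["patient_id"].to_numpy())

    dia = mutations[
        (mutations["timepoint"] == "diagnosis")
        & mutations["called"]
        & mutations["patient_id"].isin(set(cohort["patient_id"]))
        & mutations["effect"].isin(NON_SILENT_EFFECTS)
    ]
    if unit == "gene":
        carrier_sets = {
            g: set(sub["patient_id"]) for g, sub in dia.groupby("gene") if g
        }
    else:
        flags = pathway_collapse(dia, pathway_map)
        carrier_sets = {
            pw: set(flags.index[flags[pw]]) for pw in flags.columns
        }

    tested = {
        u: carriers for u, carriers in carrier_sets.items()
        if len(carriers) >= min_mutated
    }
    m = len(tested)
    gray_kwargs = dict(gray_kwargs or {})

    rows = []
    for u in sorted(tested):
        carriers = tested[u]
        grouping = np.where(
            cohort["patient_id"].isin(carriers).to_numpy(), "mutated", "unmutated"
        )
        res = gray_test(surv.reset_index(drop=True), grouping, **gray_kwargs)
        rows.append(
            {
                "unit": u,
                "n_mutated": len(carriers),
                "statistic": res.statistic,
                "p": res.p,
                "bonferroni_p": min(1.0, res.p * m),
                "m": m,
                "method": res.method,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["unit", "n_mutated", "statistic", "p", "bonferroni_p", "m", "method"],
    )
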