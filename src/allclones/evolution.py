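"""Paired diagnosis/relapse analysis: gained/lost/shared calls, low-AF
rescue, rising clones, clone grouping and relapse-associated genes.

A mutation called only at relapse ("relapse-gained") may pre-exist in a
minor subclone at diagnosis: deep coverage lets re-genotyped read support
below AF 2% rescue it as already present.  Symmetrically, a mutation called
only at diagnosis can leave residual low-level support at relapse.  A
mutation belongs to a rising clone when its relapse AF is at least twice
its diagnostic AF (boundary inclusive).  Clone grouping is a deterministic
algorithmic proxy for the manual clustering practitioners do: mutations are
grouped by their presence pattern across timepoints, then single-linkage
joined when every per-timepoint AF difference is within a tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NON_SILENT_EFFECTS, TIMEPOINTS

__all__ = [
    "EvolutionCall",
    "CloneGroup",
    "classify_status",
    "rescue_low_af",
    "flag_rising",
    "group_clones",
    "relapse_associated_genes",
    "driver_gain_loss_summary",
    "calls_to_frame",
]


@dataclass
class EvolutionCall:
    """Per-mutation diagnosis/relapse status for one paired patient."""

    patient_id: str
    key: tuple  # (chrom, pos, ref, alt)
    gene: str | None
    effect: str
    status: str  # diagnosis_only | shared | relapse_gained
    reference_timepoint: str  # timepoint the gain/loss is judged against
    called_timepoints: tuple = ()
    af_by_timepoint: dict = field(default_factory=dict)
    support_by_timepoint: dict = field(default_factory=dict)  # tp -> (alt, depth)
    rescued_at_earlier_timepoint: bool = False
    residual_at_relapse: bool = False
    rising: bool = False

    def __post_init__(self) -> None:
        if self.rescued_at_earlier_timepoint and self.status != "relapse_gained":
            raise ValueError("rescued implies relapse_gained")
        if self.residual_at_relapse and self.status != "diagnosis_only":
            raise ValueError("residual implies diagnosis_only")


@dataclass
class CloneGroup:
    clone_id: int
    patient_id: str
    member_keys: list
    af_trajectory: dict  # timepoint -> mean AF of members (NaN if absent)
    fate: str  # eradicated | persisting | expanding


def _patient_timepoints(frame: pd.DataFrame) -> list[str]:
    """Timepoints sampled for a patient, inferred from their records.

    Any relapse record implies the diagnostic sample exists (a patient
    can carry zero called mutations at diagnosis), so the chain runs from
    diagnosis up to the latest observed timepoint.
    """
    present = set(frame["timepoint"])
    if "relapse2" in present:
        return list(TIMEPOINTS)
    if "relapse1" in present:
        return ["diagnosis", "relapse1"]
    return ["diagnosis"] if present else []


def classify_status(mutations: pd.DataFrame) -> list[EvolutionCall]:
    """Classify every mutation of every paired patient.

    ``mutations`` holds all records (all timepoints) with ``called`` flags;
    each patient must have records at two or more timepoints.  Shared =
    called at diagnosis and at any relapse; relapse-gained = called only at
    relapse; diagnosis-only = called only at diagnosis.  A mutation called
    only at the second relapse is classified against the first relapse the
    same way (relapse-gained with reference_timepoint="relapse1").
    """
    calls: list[EvolutionCall] = []
    for pid, pf in mutations.groupby("patient_id"):
        tps = _patient_timepoints(pf)
        if len(tps) < 2:
            raise ValueError(f"patient {pid} has a single timepoint")
        for key, kf in pf.groupby(["chrom", "pos", "ref", "alt"]):
            called_at = set(kf.loc[kf["called"], "timepoint"])
            af_by_tp: dict[str, float] = {}
            support: dict[str, tuple] = {}
            for r in kf.itertuples(index=False):
                af_by_tp[r.timepoint] = (
                    float(r.af) if r.af is not None and not pd.isna(r.af) else np.nan
                )
                support[r.timepoint] = (int(r.alt_reads), int(r.depth))
            if not called_at:
                continue
            relapse_calls = called_at & {"relapse1", "relapse2"}
            if "diagnosis" in called_at and relapse_calls:
                status, ref_tp = "shared", "diagnosis"
            elif "diagnosis" in called_at:
                status, ref_tp = "diagnosis_only", "diagnosis"
            elif called_at == {"relapse2"} and "relapse1" in tps:
                status, ref_tp = "relapse_gained", "relapse1"
            else:
                status, ref_tp = "relapse_gained", "diagnosis"
            first = kf.iloc[0]
            calls.append(
                EvolutionCall(
                    patient_id=str(pid),
                    key=tuple(key),
                    gene=None if pd.isna(first["gene"]) else str(first["gene"]),
                    effect=str(first["effect"]),
                    status=status,
                    reference_timepoint=ref_tp,
                    called_timepoints=tuple(
                        tp for tp in TIMEPOINTS if tp in called_at
                    ),
                    af_by_timepoint=af_by_tp,
                    support_by_timepoint=support,
                )
            )
    return calls


def rescue_low_af(
    calls: Sequence[EvolutionCall],
    af_ceiling: float = 0.02,
    min_alt_reads: int = 2,
) -> list[EvolutionCall]:
    """Flag low-level read support at the timepoint where a call is absent.

    A relapse-gained mutation with re-genotyped support at its reference
    timepoint (alt reads >= ``min_alt_reads`` and AF < ``af_ceiling``) is
    rescued: it pre-existed in a minor subclone.  A diagnosis-only mutation
    with the same level of support at relapse is residual.  Missing read
    support leaves the flag False.
    """
    out = []
    for call in calls:
        rescued = call.rescued_at_earlier_timepoint
        residual = call.residual_at_relapse
        if call.status == "relapse_gained":
            tp = call.reference_timepoint
            alt, depth = call.support_by_timepoint.get(tp, (0, 0))
            af = alt / depth if depth > 0 else 0.0
            rescued = alt >= min_alt_reads and af < af_ceiling
        elif call.status == "diagnosis_only":
            for tp in ("relapse1", "relapse2"):
                alt, depth = call.support_by_timepoint.get(tp, (0, 0))
                af = alt / depth if depth > 0 else 0.0
                if alt >= min_alt_reads and af < af_ceiling:
                    residual = True
        out.append(
            dataclasses.replace(
                call,
                rescued_at_earlier_timepoint=rescued,
                residual_at_relapse=residual,
            )
        )
    return out


def flag_rising(calls: Sequence[EvolutionCall]) -> list[EvolutionCall]:
    """Mark shared mutations whose relapse AF is >= twice the diagnostic AF.

    The rule applies only to mutations called at both timepoints; rescued
    mutations are rising by construction and reported separately to avoid
    dividing by near-zero AFs.
    """
    out = []
    for call in calls:
        rising = call.rising
        if call.status == "shared":
            af_dia = call.af_by_timepoint.get("diagnosis", np.nan)
            af_rel = call.af_by_timepoint.get("relapse1", np.nan)
            if np.isnan(af_rel):
                af_rel = call.af_by_timepoint.get("relapse2", np.nan)
            if af_dia > 0 and not np.isnan(af_rel):
                rising = bool(af_rel >= 2.0 * af_dia)
        out.append(dataclasses.replace(call, rising=rising))
    return out


def group_clones(
    calls: Sequence[EvolutionCall], af_tolerance: float = 0.05
) -> list[CloneGroup]:
    """Deterministic clone grouping per patient.

    Mutations are first split by presence pattern (which timepoints they are
    called at), then single-linkage merged when their AF trajectories differ
    by at most ``af_tolerance`` at every shared timepoint.  Fate:
    eradicated if the clone is absent (and unrescued) at the last timepoint,
    expanding if any member is rising or rescued, else persisting.
    Independent of input order.
    """
    clones: list[CloneGroup] = []
    next_id = 0
    by_patient: dict[str, list[EvolutionCall]] = {}
    for c in calls:
        by_patient.setdefault(c.patient_id, []).append(c)
    for pid in sorted(by_patient):
        pcalls = sorted(by_patient[pid], key=lambda c: c.key)
        tps = sorted(
            {tp for c in pcalls for tp in c.af_by_timepoint},
            key=TIMEPOINTS.index,
        )
        patterns: dict[tuple, list[EvolutionCall]] = {}
        for c in pcalls:
            pattern = tuple(tp in c.called_timepoints for tp in tps)
            patterns.setdefault(pattern, []).append(c)
        for pattern in sorted(patterns):
            members = patterns[pattern]
            groups = _single_linkage(members, tps, af_tolerance)
            for grp in groups:
                traj = {
                    tp: float(
                        np.nanmean(
                            [m.af_by_timepoint.get(tp, np.nan) for m in grp]
                        )
                    )
                    if any(not np.isnan(m.af_by_timepoint.get(tp, np.nan)) for m in grp)
                    else np.nan
                    for tp in tps
                }
                last_tp = tps[-1]
                called_last = pattern[tps.index(last_tp)]
                rescued_any = any(m.rescued_at_earlier_timepoint for m in grp)
                residual_any = any(m.residual_at_relapse for m in grp)
                rising_any = any(m.rising for m in grp)
                if not called_last and not residual_any:
                    fate = "eradicated"
                elif rising_any or rescued_any:
                    fate = "expanding"
                else:
                    fate = "persisting"
                clones.append(
                    CloneGroup(
                        clone_id=next_id,
                        patient_id=pid,
                        member_keys=[m.key for m in grp],
                        af_trajectory=traj,
                        fate=fate,
                    )
                )
                next_id += 1
    return clones


def _single_linkage(
    members: list[EvolutionCall], tps: list[str], tol: float
) -> list[list[EvolutionCall]]:
    n = len(members)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def close(a: EvolutionCall, b: EvolutionCall) -> bool:
        for tp in tps:
            x = a.af_by_timepoint.get(tp, np.nan)
            y = b.af_by_timepoint.get(tp, np.nan)
            if np.isnan(x) or np.isnan(y):
                continue
            if abs(x - y) > tol:
                return False
        return True

    for i in range(n):
        for j in range(i + 1, n):
            if close(members[i], members[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[EvolutionCall]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(members[i])
    return [groups[r] for r in sorted(groups)]


def relapse_associated_genes(
    calls: Sequence[EvolutionCall],
    diagnostic_mutations: pd.DataFrame,
    patients: pd.DataFrame,
) -> pd.DataFrame:
    """Apply the two relapse-association criteria to every gained gene.

    Criterion 1: >= 2 non-silent relapse-gained mutations in the gene.
    Criterion 2: >= 1 relapse-gained mutation plus additional non-silent
    diagnostic mutations (diagnostic or extension cohort) in patients that
    relapsed — voided if any same-immunophenotype patient who remained in
    CR1 carries a non-silent diagnostic mutation in the gene.
    """
    pat = patients.set_index("patient_id")
    gained = [
        c for c in calls
        if c.status == "relapse_gained" and c.gene and c.effect in NON_SILENT_EFFECTS
    ]
    gained_by_gene: dict[str, list] = {}
    for c in gained:
        gained_by_gene.setdefault(c.gene, []).append(c)

    dia_ns = diagnostic_mutations[
        (diagnostic_mutations["timepoint"] == "diagnosis")
        & diagnostic_mutations["called"]
        & diagnostic_mutations["effect"].isin(NON_SILENT_EFFECTS)
        & diagnostic_mutations["gene"].notna()
    ]

    rows = []
    for gene in sorted(gained_by_gene):
        n_gained = len(gained_by_gene[gene])
        crit1 = n_gained >= 2
        phenos_gained = {
            pat.loc[c.patient_id, "immunophenotype"]
            for c in gained_by_gene[gene]
            if c.patient_id in pat.index
        }
        carriers = dia_ns.loc[dia_ns["gene"] == gene, "patient_id"].unique()
        relapsed_extra = False
        cr1_conflict = False
        for pid in carriers:
            if pid not in pat.index:
                continue
            outcome = pat.loc[pid, "outcome"]
            pheno = pat.loc[pid, "immunophenotype"]
            if outcome == "relapse":
                relapsed_extra = True
            if outcome == "CR1" and pheno in phenos_gained:
                cr1_conflict = True
        crit2 = n_gained >= 1 and relapsed_extra and not cr1_conflict
        rows.append(
            {
                "gene": gene,
                "n_relapse_gained": n_gained,
                "criterion1": crit1,
                "criterion2": crit2,
                "flagged": crit1 or crit2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "n_relapse_gained", "criterion1", "criterion2", "flagged"],
    )


def driver_gain_loss_summary(
    calls: Sequence[EvolutionCall], driver_genes: Sequence[str]
) -> pd.DataFrame:
    """Per driver gene: non-silent mutations lost and gained at relapse."""
    driver_genes = list(driver_genes)
    lost = {g: 0 for g in driver_genes}
    gained = {g: 0 for g in driver_genes}
    for c in calls:
        if c.gene not in lost or c.effect not in NON_SILENT_EFFECTS:
            continue
        if c.status == "diagnosis_only":
            lost[c.gene] += 1
        elif c.status == "relapse_gained":
            gained[c.gene] += 1
    return pd.DataFrame(
        {"gene": driver_genes,
         "lost": [lost[g] for g in driver_genes],
         "gained": [gained[g] for g in driver_genes]}
    ).set_index("gene")


def calls_to_frame(calls: Sequence[EvolutionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "patient_id": c.patient_id,
                "chrom": c.key[0],
                "pos": c.key[1],
                "ref": c.key[2],
                "alt": c.key[3],
                "gene": c.gene,
                "effect": c.effect,
                "status": c.status,
                "reference_timepoint": c.reference_timepoint,
                "rescued": c.rescued_at_earlier_timepoint,
                "residual": c.residual_at_relapse,
                "rising": c.rising,
                "af_diagnosis": c.af_by_timepoint.get("diagnosis", np.nan),
                "af_relapse1": c.af_by_timepoint.get("relapse1", np.nan),
                "af_relapse2": c.af_by_timepoint.get("relapse2", np.nan),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "chrom", "pos", "ref", "alt", "gene", "effect",
                 "status", "reference_timepoint", "rescued", "residual", "rising",
                 "af_diagnosis", "af_relapse1", "af_relapse2"],
    )
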