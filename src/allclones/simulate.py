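"""Synthetic targeted-panel leukemia cohorts with ground truth.

The generator emits the statistical structure the downstream analyses
assume: subtype-structured mutation burdens (negative binomial, higher mean
in the T immunophenotype), a bimodal allele-fraction structure (founder
mutations near blast/2, hemizygous chrX-male and mitochondrial sites near
blast, subclones below a configurable ceiling), trinucleotide contexts drawn
from per-group signature mixtures, driver genes spiked per subtype, paired
relapse samples with gained/lost/rescued/rising mutations, and
competing-risks outcomes with an elevated relapse hazard for patients
carrying a mutation in a designated pathway.

Every emitted mutation has exactly one ground-truth record, and all output
is reproducible from the config seed.  The distributional choices are
stand-ins chosen to be realistic for deep (~638x) panel data; no generative
model is claimed for the real study populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .io import MutationRecord, PatientMeta
from .signatures import CONTEXTS_96, revcomp, synthetic_reference_catalogue

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_relapse_pairs",
    "simulate_outcomes",
    "simulate_driver_spike_cohort",
    "default_gene_models",
    "default_pathway_map",
]

#: Diagnostic-cohort subtype composition (patients per subtype).
DEFAULT_SUBTYPE_COUNTS = {
    "T-ALL": 24,
    "HeH": 47,
    "t(12;21)": 36,
    "other": 22,
    "normal": 19,
    "t(9;22)": 8,
    "11q23/MLL": 4,
    "iAMP21": 4,
    "t(1;19)": 4,
    "dic(9;20)": 3,
    "gt67chr": 1,
}

#: Known driver genes spiked per subtype (chrX genes give hemizygous AFs in
#: males).
DEFAULT_DRIVERS = {
    "T-ALL": ["NOTCH1", "PTEN", "PHF6", "FBXW7", "DNM2", "RPL10"],
    "HeH": ["NRAS", "KRAS", "PTPN11", "FLT3", "SYNE1", "CREBBP"],
    "t(12;21)": ["WHSC1"],
    "normal": ["NRAS", "IL7R"],
    "other": ["KMT2D", "ATRX", "EP300"],
    "t(9;22)": ["KRAS"],
    "11q23/MLL": ["NRAS"],
    "iAMP21": ["KRAS"],
    "t(1;19)": ["NRAS"],
    "dic(9;20)": ["KRAS", "NRAS"],
    "gt67chr": ["KRAS"],
}

_KNOWN_GENE_CHROMS = {
    "NOTCH1": "9", "PTEN": "10", "PHF6": "X", "FBXW7": "4", "DNM2": "19",
    "RPL10": "X", "NRAS": "1", "KRAS": "12", "PTPN11": "12", "FLT3": "13",
    "CREBBP": "16", "KMT2D": "12", "WHSC1": "4", "IL7R": "5", "ATRX": "X",
    "SYNE1": "6", "FUBP1": "1", "DNAH5": "5", "ABCB5": "7", "EP300": "22",
    "NOTCH2": "1", "MAML2": "11", "HDAC2": "6", "DTX1": "12", "NT5C2": "10",
    "SH2B3": "12", "ETV6": "12", "EBF1": "5", "AFF3": "2", "ARID1A": "1",
    "MUC5B": "11", "MT-ND5": "MT",
}

_SIGNATURE_GROUP_OF_SUBTYPE = {
    "T-ALL": "T-ALL",
    "HeH": "HeH",
    "t(12;21)": "t(12;21)",
    "normal": "normal",
}


def _signature_group(subtype: str) -> str:
    return _SIGNATURE_GROUP_OF_SUBTYPE.get(subtype, "BCP-ALL")


def _default_mixtures() -> dict[str, dict[str, float]]:
    base = {"CpG_deamination": 0.55, "Flat": 0.45}
    return {
        "T-ALL": {"ApCpG_CtoT": 0.35, "CpG_deamination": 0.35, "Flat": 0.30},
        "BCP-ALL": dict(base),
        "HeH": dict(base),
        "normal": dict(base),
        # APOBEC-type C>G at TpCpN specifically in the t(12;21) group.
        "t(12;21)": {"CpG_deamination": 0.35, "APOBEC": 0.35, "Flat": 0.30},
    }


@dataclass
class SimConfig:
    """Study-condition parameters for the cohort generator."""

    seed: int = 0
    n_patients_by_subtype: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_COUNTS)
    )
    burden_mean_by_phenotype: dict = field(
        default_factory=lambda: {"T": 6.4, "BCP": 3.5}
    )
    burden_dispersion: float = 1.5
    blast_range: tuple = (0.80, 0.95)
    subclone_count_range: tuple = (1, 3)
    subclonal_af_ceiling: float = 0.30
    clonal_fraction_by_phenotype: dict = field(
        default_factory=lambda: {"T": 0.65, "BCP": 0.40}
    )
    driver_genes_by_subtype: dict = field(default_factory=lambda: dict(DEFAULT_DRIVERS))
    driver_spike_prob: float = 0.55
    signature_mixtures_by_group: dict = field(default_factory=_default_mixtures)
    relapse_pair_fraction: float = 0.5
    gained_per_relapse_mean: float = 5.0
    lost_per_relapse_mean: float = 3.6
    rescue_fraction: float = 0.21
    residual_fraction: float = 0.09
    second_relapse_fraction: float = 0.25
    pathway_hazard_ratio: float = 3.0
    hazard_pathway: str = "Notch"
    baseline_relapse_hazard: float = 0.035
    competing_hazard: float = 0.008
    censor_time_years: float = 10.0
    depth_mean: float = 638.0
    depth_dispersion: float = 8.0
    n_genes: int = 872
    noise_free: bool = False

    def __post_init__(self) -> None:
        for p in (
            self.driver_spike_prob,
            self.relapse_pair_fraction,
            self.rescue_fraction,
            self.residual_fraction,
            self.second_relapse_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.baseline_relapse_hazard <= 0 or self.competing_hazard <= 0:
            raise ValueError("hazards must be > 0")
        if self.pathway_hazard_ratio <= 0:
            raise ValueError("pathway_hazard_ratio must be > 0")
        if not self.subclonal_af_ceiling < 0.5:
            raise ValueError("subclonal_af_ceiling must be < 0.5")
        if self.burden_dispersion <= 0:
            raise ValueError("burden_dispersion must be > 0")
        if not self.n_patients_by_subtype:
            raise ValueError("empty subtype map")


@dataclass
class SimTruth:
    """Ground truth for every emitted mutation, patient and relapse pair."""

    mutations: pd.DataFrame
    patients: pd.DataFrame
    contexts: dict
    pairs: pd.DataFrame | None = None

    @property
    def reference_fetcher(self) -> Callable[[str, int], str]:
        contexts = self.contexts

        def fetch(chrom: str, pos: int) -> str:
            try:
                return contexts[(str(chrom), int(pos))]
            except KeyError:
                raise KeyError(f"no simulated flanks at {chrom}:{pos}") from None

        return fetch


def default_gene_models(n_genes: int = 872, seed: int = 20160831) -> pd.DataFrame:
    """Deterministic synthetic gene panel: known genes plus fillers.

    Returns a frame with gene, chrom, start (1-based layout coordinate) and
    coding_length_bp.  Genes are laid out non-overlapping per chromosome.
    """
    rng = np.random.default_rng(seed)
    genes = list(_KNOWN_GENE_CHROMS)
    chroms = [_KNOWN_GENE_CHROMS[g] for g in genes]
    n_fill = max(0, n_genes - len(genes))
    autosomes = [str(c) for c in range(1, 23)]
    for i in range(n_fill):
        genes.append(f"GENE{i + 1:04d}")
        chroms.append(autosomes[int(rng.integers(len(autosomes)))])
    lengths = np.clip(
        rng.lognormal(mean=np.log(1500), sigma=0.6, size=len(genes)), 300, 30000
    ).astype(int)
    offsets: dict[str, int] = {}
    starts = []
    for chrom, length in zip(chroms, lengths):
        start = offsets.get(chrom, 1)
        starts.append(start)
        offsets[chrom] = start + int(length) + 10_000
    return pd.DataFrame(
        {"gene": genes, "chrom": chroms, "start": starts, "coding_length_bp": lengths}
    )


def default_pathway_map(gene_models: pd.DataFrame | None = None,
                        seed: int = 20160831) -> pd.DataFrame:
    """Gene→pathway map: curated leukemia pathways plus random filler sets."""
    rows = []
    curated = {
        "Notch": ["NOTCH1", "NOTCH2", "CREBBP", "EP300", "MAML2", "HDAC2", "DTX1"],
        "Ras": ["KRAS", "NRAS", "PTPN11", "FLT3"],
        "JAK-STAT": ["IL7R", "SH2B3"],
        "Chromatin": ["KMT2D", "ATRX", "ARID1A", "WHSC1", "PHF6"],
    }
    for pw, members in curated.items():
        for g in members:
            rows.append({"gene": g, "pathway_id": pw, "pathway_name": pw})
    if gene_models is not None:
        rng = np.random.default_rng(seed)
        fillers = [g for g in gene_models["gene"] if g.startswith("GENE")]
        assignment = rng.integers(0, 20, size=len(fillers))
        for g, a in zip(fillers, assignment):
            rows.append(
                {"gene": g, "pathway_id": f"PW{a + 1:02d}",
                 "pathway_name": f"PW{a + 1:02d}"}
            )
    return pd.DataFrame(rows, columns=["gene", "pathway_id", "pathway_name"])


def _neg_binomial(rng: np.random.Generator, mean: float, dispersion: float,
                  size: int | None = None):
    # dispersion r: var = mean + mean^2 / r
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


_SNV_EFFECTS = ["nsSNV", "silent", "nonsense", "splice", "noncoding"]
_SNV_EFFECT_P = [0.58, 0.22, 0.05, 0.05, 0.10]
_INDEL_EFFECTS = ["frameshift", "nonframeshift_indel", "noncoding"]
_INDEL_EFFECT_P = [0.60, 0.30, 0.10]


class _Emitter:
    """Shared machinery for placing mutations on the synthetic gene layout."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.genes = default_gene_models(config.n_genes)
        self.gene_info = {
            g.gene: (g.chrom, g.start, g.coding_length_bp)
            for g in self.genes.itertuples(index=False)
        }
        self.length_weights = (
            self.genes["coding_length_bp"] / self.genes["coding_length_bp"].sum()
        ).to_numpy()
        self.catalogue = synthetic_reference_catalogue()
        self.contexts: dict[tuple[str, int], str] = {}
        self.used_positions: set[tuple[str, int]] = set()
        self._mixture_cache: dict[str, np.ndarray] = {}

    def mixture_probs(self, group: str) -> np.ndarray:
        if group not in self._mixture_cache:
            mix = self.config.signature_mixtures_by_group.get(group)
            if mix is None:
                mix = {"Flat": 1.0}
            v = np.zeros(96)
            for name, w in mix.items():
                v += w * self.catalogue.loc[name].to_numpy()
            self._mixture_cache[group] = v / v.sum()
        return self._mixture_cache[group]

    def place(self, gene: str) -> tuple[str, int]:
        chrom, start, length = self.gene_info[gene]
        for _ in range(50):
            pos = int(start + self.rng.integers(0, length))
            if (chrom, pos) not in self.used_positions:
                self.used_positions.add((chrom, pos))
                return chrom, pos
        raise RuntimeError(f"could not place a unique position in {gene}")

    def pick_gene(self) -> str:
        idx = int(self.rng.choice(len(self.genes), p=self.length_weights))
        return str(self.genes["gene"].iloc[idx])

    def make_variant(self, group: str, force_non_silent: bool = False):
        """Draw (ref, alt, variant_class, effect, context_label) for a site."""
        rng = self.rng
        if not force_non_silent and rng.random() < 0.066:
            # indel (study proportion: 69 of 1042 calls)
            if rng.random() < 0.5:
                ref, alt, vclass = "A", "AT", "insertion"
            else:
                ref, alt, vclass = "AT", "A", "deletion"
            effect = str(rng.choice(_INDEL_EFFECTS, p=_INDEL_EFFECT_P))
            return ref, alt, vclass, effect, None
        label = CONTEXTS_96[int(rng.choice(96, p=self.mixture_probs(group)))]
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        trinuc = five + ref + three
        if rng.random() < 0.5:  # emit on the purine strand
            trinuc = revcomp(trinuc)
            ref, alt = revcomp(ref), revcomp(alt)
        if force_non_silent:
            effect = str(rng.choice(["nsSNV", "nonsense", "splice"], p=[0.8, 0.1, 0.1]))
        else:
            effect = str(rng.choice(_SNV_EFFECTS, p=_SNV_EFFECT_P))
        return ref, alt, "SNV", effect, trinuc

    def reads(self, af: float) -> tuple[int, int, float]:
        """(alt_reads, depth, recorded af) under the read-count layer."""
        depth = max(30, int(_neg_binomial(
            self.rng, self.config.depth_mean, self.config.depth_dispersion)))
        if self.config.noise_free:
            alt = int(round(af * depth))
            return alt, depth, af
        alt = int(self.rng.binomial(depth, min(af, 1.0)))
        return alt, depth, alt / depth


def _hemizygous(chrom: str, sex: str) -> bool:
    return (chrom == "X" and sex == "M") or chrom in ("MT", "M")


def simulate_cohort(config: SimConfig) -> tuple[list[MutationRecord], list[PatientMeta], SimTruth]:
    """Generate diagnostic samples for a full cohort with ground truth."""
    if not config.n_patients_by_subtype:
        raise ValueError("empty subtype map")
    rng = np.random.default_rng(config.seed)
    em = _Emitter(config, rng)

    pathway_map = default_pathway_map(em.genes)
    hazard_genes = set(
        pathway_map.loc[pathway_map["pathway_id"] == config.hazard_pathway, "gene"]
    )

    mutations: list[MutationRecord] = []
    patients: list[PatientMeta] = []
    truth_rows: list[dict] = []
    patient_rows: list[dict] = []

    pid_counter = 0
    for subtype, n in sorted(config.n_patients_by_subtype.items()):
        phenotype = "T" if subtype == "T-ALL" else "BCP"
        group = _signature_group(subtype)
        for _ in range(int(n)):
            pid_counter += 1
            pid = f"SIM_{pid_counter:04d}"
            sex = "M" if rng.random() < 0.5 else "F"
            age = float(
                np.clip(rng.gamma(4.0, 2.5 if phenotype == "T" else 1.7), 0.3, 17.9)
            )
            blast = float(rng.uniform(*config.blast_range))

            n_mut = int(_neg_binomial(
                rng, config.burden_mean_by_phenotype[phenotype],
                config.burden_dispersion,
            ))

            # subclone AF levels for this patient
            k_sub = int(rng.integers(config.subclone_count_range[0],
                                     config.subclone_count_range[1] + 1))
            sub_afs = np.sort(
                rng.uniform(0.02, config.subclonal_af_ceiling * blast, size=k_sub)
            )[::-1]

            # spike drivers: carve designated driver mutations out of the burden
            spike_genes: list[str] = []
            subtype_drivers = config.driver_genes_by_subtype.get(subtype, [])
            if subtype_drivers and n_mut > 0 and rng.random() < config.driver_spike_prob:
                n_spike = min(n_mut, 1 + int(rng.random() < 0.3))
                spike_genes = [
                    str(g) for g in rng.choice(subtype_drivers, size=n_spike)
                ]

            clonal_p = config.clonal_fraction_by_phenotype[phenotype]
            pat_genes: set[str] = set()
            for j in range(n_mut):
                is_driver = j < len(spike_genes)
                gene = spike_genes[j] if is_driver else em.pick_gene()
                pat_genes.add(gene)
                chrom, pos = em.place(gene)
                ref, alt, vclass, effect, trinuc = em.make_variant(
                    group, force_non_silent=is_driver
                )
                if trinuc is not None:
                    em.contexts[(chrom, pos)] = trinuc
                clonal = is_driver or rng.random() < clonal_p
                hemi = _hemizygous(chrom, sex)
                if clonal:
                    clone_id = 0
                    af_true = blast if hemi else blast / 2
                else:
                    clone_id = 1 + int(rng.integers(k_sub))
                    af_true = float(sub_afs[clone_id - 1])
                    if hemi:
                        af_true = min(2 * af_true, 0.95)
                alt_reads, depth, af_obs = em.reads(af_true)
                mutations.append(
                    MutationRecord(
                        patient_id=pid, sample_id=f"{pid}-dx", timepoint="diagnosis",
                        chrom=chrom, pos=pos, ref=ref, alt=alt,
                        variant_class=vclass, effect=effect, gene=gene,
                        af=af_obs, alt_reads=alt_reads, depth=depth, called=True,
                    )
                )
                truth_rows.append(
                    {
                        "patient_id": pid, "chrom": chrom, "pos": pos,
                        "ref": ref, "alt": alt, "gene": gene,
                        "clone_id": clone_id, "true_af": af_true,
                        "clonal": clonal, "is_driver": is_driver,
                        "context": trinuc,
                    }
                )

            # outcome from cause-specific exponential hazards
            in_hazard_group = bool(pat_genes & hazard_genes)
            h_rel = config.baseline_relapse_hazard * (
                config.pathway_hazard_ratio if in_hazard_group else 1.0
            )
            t_rel = rng.exponential(1.0 / h_rel)
            t_comp = rng.exponential(1.0 / config.competing_hazard)
            t = min(t_rel, t_comp, config.censor_time_years)
            if t >= config.censor_time_years:
                outcome = "CR1"
                t = config.censor_time_years
            elif t_rel <= t_comp:
                outcome = "relapse"
            else:
                outcome = str(rng.choice(["DCR1", "SMN", "resistant"]))
            patients.append(
                PatientMeta(
                    patient_id=pid, immunophenotype=phenotype, subtype=subtype,
                    age_years=age, sex=sex, blast_fraction=blast,
                    outcome=outcome, time_to_event_years=max(t, 1e-3),
                    cohort="core",
                )
            )
            patient_rows.append(
                {
                    "patient_id": pid, "subtype": subtype, "phenotype": phenotype,
                    "signature_group": group, "hazard_group": in_hazard_group,
                    "blast_fraction": blast, "n_subclones": k_sub,
                }
            )

    truth = SimTruth(
        mutations=pd.DataFrame(
            truth_rows,
            columns=["patient_id", "chrom", "pos", "ref", "alt", "gene", "clone_id",
                     "true_af", "clonal", "is_driver", "context"],
        ),
        patients=pd.DataFrame(patient_rows),
        contexts=em.contexts,
    )
    # keep the emitter so relapse simulation can extend the same layout
    truth._emitter = em  # type: ignore[attr-defined]
    return mutations, patients, truth


def simulate_relapse_pairs(
    mutations: list[MutationRecord],
    patients: list[PatientMeta],
    truth: SimTruth,
    config: SimConfig,
) -> tuple[list[MutationRecord], SimTruth]:
    """Add relapse samples for a fraction of relapsed patients.

    Returns the extended mutation list (diagnostic records plus relapse-
    timepoint records, low-level rescue/residual support rows included) and
    the truth updated with per-pair status/rescued/residual/rising labels.
    """
    rng = np.random.default_rng((config.seed * 1000003 + 7) % (2**31))
    em: _Emitter = getattr(truth, "_emitter", None) or _Emitter(config, rng)
    em.rng = rng

    relapsed = [p for p in patients if p.outcome == "relapse"]
    if not relapsed:
        raise ValueError("no relapsed patients to pair")
    n_pairs = max(1, int(round(config.relapse_pair_fraction * len(relapsed))))
    order = rng.permutation(len(relapsed))
    selected = [relapsed[i] for i in order[:n_pairs]]

    out = list(mutations)
    pair_rows: list[dict] = []
    truth_mut = truth.mutations

    for pat in selected:
        pid = pat.patient_id
        group = _signature_group(pat.subtype)
        dia_truth = truth_mut[truth_mut["patient_id"] == pid]
        dia_records = {
            r.key: r for r in mutations
            if r.patient_id == pid and r.timepoint == "diagnosis"
        }
        blast_rel = float(rng.uniform(*config.blast_range))

        keys = list(dia_records)
        sub_clones = sorted(
            {int(c) for c in dia_truth["clone_id"] if c > 0}
        )
        # choose whole subclones to eradicate, keeping at least one alive
        n_lost_target = int(rng.poisson(config.lost_per_relapse_mean))
        lost_keys: set = set()
        if sub_clones and n_lost_target > 0:
            eradicable = sub_clones[1:] if len(sub_clones) > 1 else []
            eradicable = [eradicable[i] for i in rng.permutation(len(eradicable))]
            for clone in eradicable:
                clone_keys = {
                    (t.chrom, t.pos, t.ref, t.alt)
                    for t in dia_truth.itertuples(index=False)
                    if t.clone_id == clone
                }
                if len(lost_keys) >= n_lost_target:
                    break
                lost_keys |= clone_keys
        # top up with individual subclonal mutations from the surviving pool?
        # deliberately not: losses act on whole clones to keep truth coherent.

        surviving_subclones = [c for c in sub_clones if not any(
            (t.chrom, t.pos, t.ref, t.alt) in lost_keys
            for t in dia_truth.itertuples(index=False) if t.clone_id == c
        )]
        rising_clone = (
            int(rng.choice(surviving_subclones)) if surviving_subclones else None
        )

        clone_factor: dict[int, float] = {}
        for key in keys:
            trow = dia_truth[
                (dia_truth["chrom"] == key[0]) & (dia_truth["pos"] == key[1])
            ].iloc[0]
            clone = int(trow["clone_id"])
            dia_rec = dia_records[key]
            af_dia = dia_rec.af if dia_rec.af is not None else 0.0
            if key in lost_keys:
                status, af_rel = "diagnosis_only", None
                residual = bool(rng.random() < config.residual_fraction)
                if residual:
                    depth = max(30, int(_neg_binomial(rng, config.depth_mean,
                                                      config.depth_dispersion)))
                    alt = max(2, int(round(depth * rng.uniform(0.004, 0.015))))
                    out.append(replace(
                        dia_rec, sample_id=f"{pid}-r1", timepoint="relapse1",
                        af=alt / depth, alt_reads=alt, depth=depth, called=False,
                    ))
                pair_rows.append({
                    "patient_id": pid, "chrom": key[0], "pos": key[1],
                    "ref": key[2], "alt": key[3], "gene": dia_rec.gene,
                    "effect": dia_rec.effect, "status": status,
                    "rescued": False, "residual": residual, "rising": False,
                    "af_diagnosis": af_dia, "af_relapse1": None,
                })
                continue
            # shared mutation: relapse AF by clone
            if clone == 0:
                hemi = _hemizygous(key[0], pat.sex)
                af_rel = blast_rel if hemi else blast_rel / 2
            else:
                if clone not in clone_factor:
                    if clone == rising_clone:
                        clone_factor[clone] = float(rng.uniform(2.0, 3.0))
                    else:
                        clone_factor[clone] = float(rng.uniform(0.7, 1.6))
                af_rel = min(clone_factor[clone] * af_dia, 0.95)
            alt, depth, af_obs = em.reads(af_rel)
            out.append(replace(
                dia_rec, sample_id=f"{pid}-r1", timepoint="relapse1",
                af=af_obs, alt_reads=alt, depth=depth, called=True,
            ))
            rising = af_dia > 0 and af_obs >= 2 * af_dia
            pair_rows.append({
                "patient_id": pid, "chrom": key[0], "pos": key[1],
                "ref": key[2], "alt": key[3], "gene": dia_rec.gene,
                "effect": dia_rec.effect, "status": "shared",
                "rescued": False, "residual": False, "rising": bool(rising),
                "af_diagnosis": af_dia, "af_relapse1": af_obs,
            })

        # relapse-gained mutations, grouped into 1-2 new clones
        n_gain = int(rng.poisson(config.gained_per_relapse_mean))
        n_new_clones = 1 + int(rng.random() < 0.4)
        new_clone_afs = rng.uniform(0.10, blast_rel / 2, size=n_new_clones)
        for _ in range(n_gain):
            gene = em.pick_gene()
            chrom, pos = em.place(gene)
            ref, alt_base, vclass, effect, trinuc = em.make_variant(group)
            if trinuc is not None:
                em.contexts[(chrom, pos)] = trinuc
                truth.contexts[(chrom, pos)] = trinuc
            af_rel = float(new_clone_afs[int(rng.integers(n_new_clones))])
            alt_r, depth_r, af_obs = em.reads(af_rel)
            out.append(MutationRecord(
                patient_id=pid, sample_id=f"{pid}-r1", timepoint="relapse1",
                chrom=chrom, pos=pos, ref=ref, alt=alt_base,
                variant_class=vclass, effect=effect, gene=gene,
                af=af_obs, alt_reads=alt_r, depth=depth_r, called=True,
            ))
            rescued = bool(rng.random() < config.rescue_fraction)
            af_dia_level = None
            if rescued:
                depth_d = max(200, int(_neg_binomial(rng, config.depth_mean,
                                                     config.depth_dispersion)))
                alt_d = max(2, int(round(depth_d * rng.uniform(0.004, 0.015))))
                af_dia_level = alt_d / depth_d
                out.append(MutationRecord(
                    patient_id=pid, sample_id=f"{pid}-dx", timepoint="diagnosis",
                    chrom=chrom, pos=pos, ref=ref, alt=alt_base,
                    variant_class=vclass, effect=effect, gene=gene,
                    af=af_dia_level, alt_reads=alt_d, depth=depth_d, called=False,
                ))
            pair_rows.append({
                "patient_id": pid, "chrom": chrom, "pos": pos,
                "ref": ref, "alt": alt_base, "gene": gene, "effect": effect,
                "status": "relapse_gained", "rescued": rescued,
                "residual": False, "rising": False,
                "af_diagnosis": af_dia_level, "af_relapse1": af_obs,
            })

    pairs = pd.DataFrame(
        pair_rows,
        columns=["patient_id", "chrom", "pos", "ref", "alt", "gene", "effect",
                 "status", "rescued", "residual", "rising",
                 "af_diagnosis", "af_relapse1"],
    )
    new_truth = SimTruth(
        mutations=truth.mutations, patients=truth.patients,
        contexts=truth.contexts, pairs=pairs,
    )
    return out, new_truth


def simulate_driver_spike_cohort(
    seed: int,
    n_passenger_genes: int = 200,
    n_driver_genes: int = 10,
    n_patients: int = 100,
    background_per_patient: float = 2.5,
    spike_patients: int = 5,
    subtype: str = "HeH",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Cohort with known spiked driver genes for screen benchmarking.

    Passenger mutations land on genes proportionally to coding length at a
    sparse panel-like background rate; each driver gene receives one
    clustered non-silent mutation in ``spike_patients`` distinct patients
    (several-fold above the per-gene background).  Returns
    (mutations, patients, gene_models, driver_gene_names).
    """
    rng = np.random.default_rng(seed)
    genes = [f"P{i:03d}" for i in range(n_passenger_genes)] + [
        f"DRV{i}" for i in range(n_driver_genes)
    ]
    lengths = np.clip(
        rng.lognormal(np.log(1500), 0.5, len(genes)), 300, 10000
    ).astype(int)
    gene_models = pd.DataFrame(
        {
            "gene": genes,
            "chrom": "1",
            "start": np.arange(len(genes)) * 20000 + 1,
            "coding_length_bp": lengths,
        }
    )
    glen = dict(zip(genes, lengths))
    gstart = dict(zip(genes, gene_models["start"]))
    weights = lengths / lengths.sum()
    effects = ["nsSNV", "silent", "noncoding", "nonsense"]
    effect_p = [0.55, 0.25, 0.15, 0.05]

    rows = []

    def emit(pid: str, gene: str, pos: int, effect: str) -> None:
        rows.append(
            {
                "patient_id": pid, "sample_id": pid, "timepoint": "diagnosis",
                "chrom": "1", "pos": pos, "ref": "C", "alt": "T",
                "variant_class": "SNV", "effect": effect, "gene": gene,
                "af": 0.4, "alt_reads": 40, "depth": 100, "called": True,
            }
        )

    for p in range(n_patients):
        pid = f"PT{p:03d}"
        for _ in range(rng.poisson(background_per_patient)):
            gene = genes[int(rng.choice(len(genes), p=weights))]
            emit(pid, gene, int(gstart[gene] + rng.integers(glen[gene])),
                 str(rng.choice(effects, p=effect_p)))
    for i in range(n_driver_genes):
        gene = f"DRV{i}"
        hotspot = int(gstart[gene] + rng.integers(glen[gene] - 60))
        for p in rng.choice(n_patients, spike_patients, replace=False):
            emit(f"PT{p:03d}", gene, hotspot + int(rng.integers(30)), "nsSNV")

    patients = pd.DataFrame(
        {
            "patient_id": [f"PT{p:03d}" for p in range(n_patients)],
            "immunophenotype": "T" if subtype == "T-ALL" else "BCP",
            "subtype": subtype,
        }
    )
    return (
        pd.DataFrame(rows),
        patients,
        gene_models,
        [f"DRV{i}" for i in range(n_driver_genes)],
    )


def simulate_outcomes(
    n_patients: int,
    n_mutated: int,
    hazard_ratio: float,
    baseline_relapse_hazard: float = 0.035,
    competing_hazard: float = 0.008,
    censor_time_years: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Competing-risks outcomes for a two-group cohort (survival helper).

    Returns a frame with patient_id, mutated, time and event
    (relapse | competing | censored); the mutated group's relapse hazard is
    multiplied by ``hazard_ratio``.
    """
    if n_mutated > n_patients:
        raise ValueError("n_mutated exceeds n_patients")
    rng = np.random.default_rng(seed)
    mutated = np.zeros(n_patients, dtype=bool)
    mutated[:n_mutated] = True
    h_rel = np.where(
        mutated, baseline_relapse_hazard * hazard_ratio, baseline_relapse_hazard
    )
    t_rel = rng.exponential(1.0 / h_rel)
    t_comp = rng.exponential(1.0 / competing_hazard, size=n_patients)
    t = np.minimum(np.minimum(t_rel, t_comp), censor_time_years)
    event = np.where(
        t >= censor_time_years, "censored",
        np.where(t_rel <= t_comp, "relapse", "competing"),
    )
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_patients)],
            "mutated": mutated,
            "time": np.maximum(t, 1e-6),
            "event": event,
        }
    )
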