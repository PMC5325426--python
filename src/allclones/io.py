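"""Domain types, somatic-filtering rules and table readers/writers.

The pipeline starts downstream of variant calling: its inputs are somatic
mutation call tables (tab-separated or VCF 4.x), patient metadata tables,
gene models, blacklists and gene→pathway maps.  All coordinates are 1-based,
fully closed, VCF-style; indels are expected left-normalized with an anchor
base.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "EFFECTS",
    "NON_SILENT_EFFECTS",
    "SUBTYPES",
    "OUTCOMES",
    "EFFECT_ALIASES",
    "MutationRecord",
    "PatientMeta",
    "GeneModel",
    "FilterPolicy",
    "classify_non_silent",
    "filter_somatic",
    "read_mutations",
    "write_mutations",
    "write_mutations_vcf",
    "read_patients",
    "write_patients",
    "read_gene_models",
    "read_blacklist",
    "read_pathway_map",
    "mutations_to_frame",
    "frame_to_mutations",
]

TIMEPOINTS = ("diagnosis", "relapse1", "relapse2")

VARIANT_CLASSES = ("SNV", "insertion", "deletion")

EFFECTS = (
    "nsSNV",
    "nonsense",
    "frameshift",
    "nonframeshift_indel",
    "splice",
    "silent",
    "noncoding",
)

#: Protein-altering effect classes; only these enter driver, relapse and
#: evolution analyses.
NON_SILENT_EFFECTS = frozenset(
    {"nsSNV", "nonsense", "frameshift", "nonframeshift_indel", "splice"}
)

SUBTYPES = (
    "HeH",
    "t(12;21)",
    "t(9;22)",
    "11q23/MLL",
    "iAMP21",
    "t(1;19)",
    "dic(9;20)",
    "gt67chr",
    "other",
    "normal",
    "T-ALL",
)

OUTCOMES = ("CR1", "relapse", "DCR1", "SMN", "resistant")

#: Lookup from common annotator consequence strings to the fixed effect
#: taxonomy.  Unknown strings are an error rather than silently "noncoding".
EFFECT_ALIASES = {
    "missense_variant": "nsSNV",
    "missense": "nsSNV",
    "nonsynonymous_snv": "nsSNV",
    "nssnv": "nsSNV",
    "stop_gained": "nonsense",
    "stopgain": "nonsense",
    "nonsense": "nonsense",
    "frameshift_variant": "frameshift",
    "frameshift_insertion": "frameshift",
    "frameshift_deletion": "frameshift",
    "frameshift": "frameshift",
    "inframe_insertion": "nonframeshift_indel",
    "inframe_deletion": "nonframeshift_indel",
    "nonframeshift_indel": "nonframeshift_indel",
    "splice_acceptor_variant": "splice",
    "splice_donor_variant": "splice",
    "splice_site": "splice",
    "splice": "splice",
    "synonymous_variant": "silent",
    "synonymous": "silent",
    "silent": "silent",
    "intron_variant": "noncoding",
    "intergenic_variant": "noncoding",
    "5_prime_utr_variant": "noncoding",
    "3_prime_utr_variant": "noncoding",
    "noncoding": "noncoding",
}

_AF_TOLERANCE = 0.01


def normalize_effect(effect: str) -> str:
    """Map an annotator consequence string onto the fixed effect taxonomy."""
    key = effect.strip()
    if key in EFFECTS:
        return key
    try:
        return EFFECT_ALIASES[key.lower()]
    except KeyError:
        raise ValueError(f"unknown effect/consequence string: {effect!r}") from None


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant in one sample at one timepoint.

    ``af`` is the mutant allele fraction; when absent it is derived from
    ``alt_reads / depth``.  ``called`` records whether the variant passed
    variant calling at this timepoint — re-genotyped low-level support
    (rescue genotyping) is represented by records with ``called=False``.
    """

    patient_id: str
    sample_id: str
    timepoint: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    effect: str
    gene: str | None
    af: float | None
    alt_reads: int
    depth: int
    called: bool = True

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint label: {self.timepoint!r}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class: {self.variant_class!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect: {self.effect!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt_reads < 0 or self.depth < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth}) "
                f"at {self.chrom}:{self.pos}"
            )
        if self.variant_class == "SNV" and self.ref == self.alt:
            raise ValueError(f"SNV with ref == alt at {self.chrom}:{self.pos}")
        if self.af is not None:
            if not 0.0 <= self.af <= 1.0:
                raise ValueError(f"af out of [0,1]: {self.af}")
            if self.depth > 0:
                empirical = self.alt_reads / self.depth
                if abs(self.af - empirical) > _AF_TOLERANCE:
                    raise ValueError(
                        f"af {self.af:.4f} inconsistent with "
                        f"alt_reads/depth = {empirical:.4f} at {self.chrom}:{self.pos}"
                    )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity within a patient: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def non_silent(self) -> bool:
        return self.effect in NON_SILENT_EFFECTS


@dataclass(frozen=True)
class PatientMeta:
    """Subtype, immunophenotype, outcome and follow-up for one patient."""

    patient_id: str
    immunophenotype: str  # "BCP" | "T"
    subtype: str
    age_years: float
    sex: str  # "M" | "F"
    blast_fraction: float
    outcome: str
    time_to_event_years: float
    cohort: str = "core"  # core | diagnostic_only | extension

    def __post_init__(self) -> None:
        if self.immunophenotype not in ("BCP", "T"):
            raise ValueError(f"unknown immunophenotype: {self.immunophenotype!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype: {self.subtype!r}")
        if (self.subtype == "T-ALL") != (self.immunophenotype == "T"):
            raise ValueError(
                f"subtype T-ALL and immunophenotype T must coincide "
                f"(patient {self.patient_id})"
            )
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome: {self.outcome!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex: {self.sex!r}")
        if not 0.0 <= self.blast_fraction <= 1.0:
            raise ValueError("blast_fraction must be in [0,1]")
        if self.age_years < 0 or self.time_to_event_years < 0:
            raise ValueError("age and follow-up must be non-negative")


@dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    coding_length_bp: int
    expressed_fpkm: float | None = None

    def __post_init__(self) -> None:
        if self.coding_length_bp <= 0:
            raise ValueError(f"coding_length_bp must be > 0 for {self.gene}")


@dataclass(frozen=True)
class FilterPolicy:
    """Somatic filter thresholds plus germline/population blacklists.

    Defaults are calling-grade; rescue genotyping deliberately bypasses them.
    """

    min_depth: int = 20
    min_alt_reads: int = 4
    min_af: float = 0.05
    germline_blacklist: frozenset = field(default_factory=frozenset)
    population_blacklist: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_alt_reads < 0 or self.min_af < 0:
            raise ValueError("filter thresholds must be >= 0")


def classify_non_silent(record: MutationRecord | str) -> bool:
    """True iff the effect is protein-altering (incl. splice sites)."""
    effect = record.effect if isinstance(record, MutationRecord) else record
    return effect in NON_SILENT_EFFECTS


def filter_somatic(
    records: Iterable[MutationRecord], policy: FilterPolicy
) -> tuple[list[MutationRecord], list[tuple[MutationRecord, str]]]:
    """Apply depth / alt-read / AF thresholds and blacklists.

    Returns ``(kept, dropped)`` where every dropped record carries exactly
    one reason tag — the first failing check in the fixed order
    depth, alt_reads, af, germline, population.
    """
    kept: list[MutationRecord] = []
    dropped: list[tuple[MutationRecord, str]] = []
    for rec in records:
        af = rec.af if rec.af is not None else (
            rec.alt_reads / rec.depth if rec.depth > 0 else 0.0
        )
        if rec.depth < policy.min_depth:
            dropped.append((rec, "depth"))
        elif rec.alt_reads < policy.min_alt_reads:
            dropped.append((rec, "alt_reads"))
        elif af < policy.min_af:
            dropped.append((rec, "af"))
        elif rec.key in policy.germline_blacklist:
            dropped.append((rec, "germline"))
        elif rec.key in policy.population_blacklist:
            dropped.append((rec, "population"))
        else:
            kept.append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = [
    "patient_id",
    "sample_id",
    "timepoint",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "effect",
    "gene",
    "af",
    "alt_reads",
    "depth",
    "called",
]


def mutations_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Tidy DataFrame with one row per (variant, sample, timepoint)."""
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    if len(frame):
        frame["pos"] = frame["pos"].astype(int)
    return frame


def frame_to_mutations(frame: pd.DataFrame) -> list[MutationRecord]:
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            af = row.af
            if af is None or pd.isna(af):
                af = row.alt_reads / row.depth if row.depth > 0 else None
            records.append(
                MutationRecord(
                    patient_id=str(row.patient_id),
                    sample_id=str(row.sample_id),
                    timepoint=str(row.timepoint),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    variant_class=str(row.variant_class),
                    effect=normalize_effect(str(row.effect)),
                    gene=None if pd.isna(row.gene) else str(row.gene),
                    af=None if af is None else float(af),
                    alt_reads=int(row.alt_reads),
                    depth=int(row.depth),
                    called=bool(row.called),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed mutation row {i + 1}: {exc}") from exc
    return records


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def read_mutations(path: str | Path, format: str | None = None) -> list[MutationRecord]:
    """Read a mutation table (TSV with the documented header, or VCF 4.x)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf",) or path.name.endswith(".vcf.gz") else "tsv"
    if format == "vcf":
        return _read_mutations_vcf(path)
    if format != "tsv":
        raise ValueError(f"unknown format: {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    frame = _read_table(path)
    missing = set(MUTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    return frame_to_mutations(frame[MUTATION_COLUMNS])


def write_mutations(records: Sequence[MutationRecord], path: str | Path,
                    header_comment: str | None = None) -> None:
    frame = mutations_to_frame(records)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


# --- VCF dialect -----------------------------------------------------------
#
# One record per (variant, sample, timepoint); the sample column is named
# ``<patient_id>|<sample_id>|<timepoint>`` and carries GT:AD:DP.  GT is 0/1
# for called variants and ./. for re-genotyped (uncalled) support.  Gene,
# effect and variant class travel in INFO.

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect class">
##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_mutations_vcf(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write one single-sample VCF body row per record (spec dialect)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for rec in records:
            info = (
                f"GENE={rec.gene if rec.gene else '.'};"
                f"EFFECT={rec.effect};VCLASS={rec.variant_class}"
            )
            gt = "0/1" if rec.called else "./."
            sample_label = f"{rec.patient_id}|{rec.sample_id}|{rec.timepoint}"
            ad = f"{rec.depth - rec.alt_reads},{rec.alt_reads}"
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{sample_label}\t{rec.ref}\t{rec.alt}\t."
                f"\tPASS\t{info}\tGT:AD:DP\t{gt}:{ad}:{rec.depth}\n"
            )


def _read_mutations_vcf(path: Path) -> list[MutationRecord]:
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MutationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise ValueError(f"malformed VCF row at line {lineno}")
            chrom, pos, vid, ref, alt, _qual, _filt, info, fmt, sample = fields[:10]
            try:
                patient_id, sample_id, timepoint = vid.split("|")
            except ValueError:
                raise ValueError(
                    f"line {lineno}: ID field must be patient|sample|timepoint"
                ) from None
            info_map = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            fmt_keys = fmt.split(":")
            fmt_vals = sample.split(":")
            fval = dict(zip(fmt_keys, fmt_vals))
            if "AD" in fval:
                ref_reads, alt_reads = (int(x) for x in fval["AD"].split(","))
                depth = int(fval.get("DP", ref_reads + alt_reads))
            elif "DP" in fval and "AF" in fval:
                depth = int(fval["DP"])
                alt_reads = round(float(fval["AF"]) * depth)
            else:
                raise ValueError(f"line {lineno}: need AD/DP or AF/DP FORMAT fields")
            if len(ref) == len(alt) == 1:
                vclass = "SNV"
            elif len(alt) > len(ref):
                vclass = "insertion"
            else:
                vclass = "deletion"
            vclass = info_map.get("VCLASS", vclass)
            gene = info_map.get("GENE", ".")
            try:
                records.append(
                    MutationRecord(
                        patient_id=patient_id,
                        sample_id=sample_id,
                        timepoint=timepoint,
                        chrom=chrom,
                        pos=int(pos),
                        ref=ref,
                        alt=alt,
                        variant_class=vclass,
                        effect=normalize_effect(info_map.get("EFFECT", "noncoding")),
                        gene=None if gene == "." else gene,
                        af=(alt_reads / depth) if depth > 0 else None,
                        alt_reads=alt_reads,
                        depth=depth,
                        called=fval.get("GT", "./.") not in ("./.", "."),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"malformed VCF row at line {lineno}: {exc}") from exc
    return records


PATIENT_COLUMNS = [
    "patient_id",
    "immunophenotype",
    "subtype",
    "age_years",
    "sex",
    "blast_fraction",
    "outcome",
    "time_to_event_years",
    "cohort",
]


def patients_to_frame(patients: Sequence[PatientMeta]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in patients], columns=PATIENT_COLUMNS)


def read_patients(path: str | Path) -> list[PatientMeta]:
    frame = _read_table(path)
    missing = set(PATIENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"patient table missing columns: {sorted(missing)}")
    out = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            out.append(
                PatientMeta(
                    patient_id=str(row.patient_id),
                    immunophenotype=str(row.immunophenotype),
                    subtype=str(row.subtype),
                    age_years=float(row.age_years),
                    sex=str(row.sex),
                    blast_fraction=float(row.blast_fraction),
                    outcome=str(row.outcome),
                    time_to_event_years=float(row.time_to_event_years),
                    cohort=str(row.cohort),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed patient row {i + 1}: {exc}") from exc
    return out


def write_patients(patients: Sequence[PatientMeta], path: str | Path) -> None:
    patients_to_frame(patients).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    frame = _read_table(path)
    out = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        gene = str(row.gene)
        if gene in seen:
            raise ValueError(f"duplicate gene name: {gene}")
        seen.add(gene)
        fpkm = getattr(row, "expressed_fpkm", None)
        out.append(
            GeneModel(
                gene=gene,
                chrom=str(row.chrom),
                coding_length_bp=int(row.coding_length_bp),
                expressed_fpkm=None if fpkm is None or pd.isna(fpkm) else float(fpkm),
            )
        )
    return out


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in models]).to_csv(
        path, sep="\t", index=False
    )


def read_blacklist(path: str | Path) -> frozenset:
    """Sorted 4-column TSV (chrom, pos, ref, alt) → site set."""
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "pos", "ref", "alt"], dtype={"chrom": str},
    )
    return frozenset(
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in frame.itertuples(index=False)
    )


def write_blacklist(sites: Iterable[tuple], path: str | Path) -> None:
    frame = pd.DataFrame(sorted(sites), columns=["chrom", "pos", "ref", "alt"])
    frame.to_csv(path, sep="\t", index=False, header=False)


def read_pathway_map(path: str | Path) -> pd.DataFrame:
    """Gene→pathway map TSV with columns gene, pathway_id[, pathway_name]."""
    frame = _read_table(path)
    if not {"gene", "pathway_id"} <= set(frame.columns):
        raise ValueError("pathway map needs columns gene, pathway_id")
    if "pathway_name" not in frame.columns:
        frame["pathway_name"] = frame["pathway_id"]
    return frame[["gene", "pathway_id", "pathway_name"]]
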