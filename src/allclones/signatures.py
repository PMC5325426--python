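"""Trinucleotide-context tabulation, panel-composition correction and NMF.

SNVs are collapsed onto the 96 pyrimidine-centered substitution classes
(6 substitution types x 16 flanking-base pairs).  Because a targeted panel
over- or under-represents particular trinucleotide motifs relative to the
whole genome, raw context counts are corrected by the ratio of genome to
panel motif frequencies before decomposition.  Signatures are then extracted
by non-negative matrix factorization (Frobenius loss, multiple random
restarts) and matched against a reference catalogue by cosine similarity,
with a complete-linkage Euclidean dendrogram as a secondary view.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import NMF

__all__ = [
    "SUBSTITUTIONS",
    "CONTEXTS_96",
    "PYRIMIDINE_TRINUCS_32",
    "ContextMatrix",
    "MotifFrequencies",
    "SignatureSet",
    "revcomp",
    "context_label",
    "motif_of_context",
    "FastaFetcher",
    "extract_contexts",
    "normalize_motifs",
    "kmer_frequencies",
    "nmf_decompose",
    "match_signatures",
    "load_reference_catalogue",
    "synthetic_reference_catalogue",
]

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical ordering: substitution-major, flanks lexicographic within.
CONTEXTS_96 = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]

#: The 32 pyrimidine-centered trinucleotides, C-centered then T-centered.
PYRIMIDINE_TRINUCS_32 = [
    f"{five}{center}{three}" for center in "CT" for five in BASES for three in BASES
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def context_label(trinuc: str, ref: str, alt: str) -> str:
    """96-class label for an SNV given its reference-centered trinucleotide.

    Purine-reference SNVs are reverse-complemented into the pyrimidine frame.
    """
    trinuc = trinuc.upper()
    ref, alt = ref.upper(), alt.upper()
    if len(trinuc) != 3 or trinuc[1] != ref:
        raise ValueError(f"trinucleotide {trinuc!r} does not center on ref {ref!r}")
    if ref == alt:
        raise ValueError("SNV with ref == alt")
    if ref in "AG":
        trinuc = revcomp(trinuc)
        ref, alt = revcomp(ref), revcomp(alt)
    label = f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"
    if label not in _CONTEXT_SET:
        raise ValueError(f"not a valid context: {label}")
    return label


_CONTEXT_SET = frozenset(CONTEXTS_96)


def motif_of_context(label: str) -> str:
    """Central pyrimidine trinucleotide of a 96-class label."""
    return label[0] + label[2] + label[6]


@dataclass
class ContextMatrix:
    """Groups x 96 trinucleotide-context counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != CONTEXTS_96:
            raise ValueError("context matrix columns must be the canonical 96 set")
        if (self.counts.values < 0).any():
            raise ValueError("context counts must be non-negative")

    @property
    def groups(self) -> list[str]:
        return list(self.counts.index)

    def total(self) -> float:
        return float(self.counts.values.sum())


@dataclass
class MotifFrequencies:
    """Frequencies of the 32 pyrimidine-centered trinucleotides in a region."""

    label: str
    freqs: pd.Series

    def __post_init__(self) -> None:
        self.freqs = self.freqs.reindex(PYRIMIDINE_TRINUCS_32)
        if self.freqs.isna().any():
            raise ValueError("motif frequencies must cover all 32 trinucleotides")
        if (self.freqs < 0).any() or self.freqs.sum() <= 0:
            raise ValueError("motif frequencies must be non-negative and sum > 0")
        self.freqs = self.freqs / self.freqs.sum()


@dataclass
class SignatureSet:
    """k signatures (rows summing to 1) with per-group exposures."""

    signatures: pd.DataFrame  # k x 96
    exposures: pd.DataFrame  # groups x k
    reconstruction_error: float


class FastaFetcher:
    """Flank fetcher backed by an indexed FASTA (1-based positions)."""

    def __init__(self, fasta_path: str | Path):
        from pyfaidx import Fasta

        self._fasta = Fasta(str(fasta_path))

    def __call__(self, chrom: str, pos: int) -> str:
        try:
            seq = self._fasta[chrom][pos - 2 : pos + 1]
        except KeyError:
            raise KeyError(f"cannot fetch flanks at {chrom}:{pos}") from None
        trinuc = str(seq).upper()
        if len(trinuc) != 3:
            raise ValueError(f"cannot fetch flanks at {chrom}:{pos} (sequence edge)")
        return trinuc


def extract_contexts(
    snvs: pd.DataFrame,
    reference_fetcher: Callable[[str, int], str],
    group_of: Mapping[str, str] | pd.Series,
    drop_recurrent: bool = True,
    isolate: Sequence[str] = (),
) -> ContextMatrix:
    """Tabulate 96-context counts per patient group.

    ``snvs`` needs columns patient_id, chrom, pos, ref, alt (SNVs only).
    Recurrent SNVs — the identical (chrom, pos, ref, alt) in more than one
    patient — are removed first.  Patients listed in ``isolate`` (e.g. a
    hypermutated outlier) form their own group regardless of ``group_of``.
    """
    required = {"patient_id", "chrom", "pos", "ref", "alt"}
    if not required <= set(snvs.columns):
        raise ValueError(f"SNV frame needs columns {sorted(required)}")
    snvs = snvs.drop_duplicates(subset=["patient_id", "chrom", "pos", "ref", "alt"])
    if drop_recurrent and len(snvs):
        npat = snvs.groupby(["chrom", "pos", "ref", "alt"])["patient_id"].transform(
            "nunique"
        )
        snvs = snvs[npat == 1]

    group_map = dict(group_of) if not isinstance(group_of, pd.Series) else group_of.to_dict()
    isolate = set(isolate)

    counts: dict[str, np.ndarray] = {}
    col_index = {c: i for i, c in enumerate(CONTEXTS_96)}
    for row in snvs.itertuples(index=False):
        pid = str(row.patient_id)
        group = pid if pid in isolate else group_map.get(pid)
        if group is None:
            continue
        trinuc = reference_fetcher(str(row.chrom), int(row.pos))
        if trinuc[1].upper() != str(row.ref).upper():
            raise ValueError(
                f"reference mismatch at {row.chrom}:{row.pos}: "
                f"FASTA has {trinuc[1]!r}, record has {row.ref!r}"
            )
        label = context_label(trinuc, str(row.ref), str(row.alt))
        counts.setdefault(group, np.zeros(96))[col_index[label]] += 1

    frame = pd.DataFrame(
        counts.values(), index=list(counts.keys()), columns=CONTEXTS_96
    )
    return ContextMatrix(frame)


def normalize_motifs(
    matrix: ContextMatrix,
    target: MotifFrequencies,
    genome: MotifFrequencies,
) -> ContextMatrix:
    """Correct context counts for panel-vs-genome motif composition.

    corrected(g, c) = counts(g, c) * genome_freq(motif(c)) / target_freq(motif(c)).
    Total counts are deliberately not conserved; swapping the two frequency
    arguments inverts the correction exactly.
    """
    if (target.freqs <= 0).any():
        zero = target.freqs.index[target.freqs <= 0][0]
        raise ValueError(f"zero target frequency for motif {zero}")
    ratio = np.array(
        [
            genome.freqs[motif_of_context(c)] / target.freqs[motif_of_context(c)]
            for c in CONTEXTS_96
        ]
    )
    corrected = matrix.counts * ratio[np.newaxis, :]
    return ContextMatrix(corrected)


def kmer_frequencies(
    fasta_path: str | Path,
    regions: pd.DataFrame | str | Path | None = None,
    label: str = "region",
) -> MotifFrequencies:
    """Pyrimidine-centered trinucleotide frequencies of a FASTA (or BED subset).

    ``regions`` is half-open 0-based BED (chrom, start, end), as a path or a
    DataFrame.  Purine-centered trinucleotides are collapsed onto their
    reverse complement; windows containing ambiguous bases are skipped.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    if regions is None:
        sequences = [str(fasta[name][:]) for name in fasta.keys()]
    else:
        if isinstance(regions, (str, Path)):
            regions = pd.read_csv(
                regions, sep="\t", header=None, comment="#",
                names=["chrom", "start", "end"], usecols=[0, 1, 2],
                dtype={"chrom": str},
            )
        if len(regions) == 0:
            raise ValueError("empty region set")
        sequences = [
            str(fasta[str(r.chrom)][int(r.start) : int(r.end)])
            for r in regions.itertuples(index=False)
        ]

    counts = pd.Series(0.0, index=PYRIMIDINE_TRINUCS_32)
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            if any(b not in BASES for b in tri):
                continue
            if tri[1] in "AG":
                tri = revcomp(tri)
            counts[tri] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous trinucleotides found")
    return MotifFrequencies(label=label, freqs=counts / counts.sum())


def nmf_decompose(
    matrix: ContextMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
    max_iter: int = 10000,
    tol: float = 1e-6,
    row_normalize: bool = False,
) -> SignatureSet:
    """Rank-k NMF of the (optionally row-normalized) context matrix.

    Frobenius-loss multiplicative updates, best of ``n_restarts`` random
    initializations; deterministic given ``seed``.  Signatures are
    normalized to sum to 1 with exposures rescaled to compensate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.counts.to_numpy(dtype=float)
    if X.sum() == 0:
        raise ValueError("all-zero context matrix")
    if row_normalize:
        X = X / X.sum(axis=1, keepdims=True)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for r in range(n_restarts):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + r,
        )
        W = model.fit_transform(X)
        H = model.components_
        err = float(model.reconstruction_err_)
        if best is None or err < best[0]:
            best = (err, W, H)
    err, W, H = best

    scale = H.sum(axis=1)
    scale[scale == 0] = 1.0
    H = H / scale[:, np.newaxis]
    W = W * scale[np.newaxis, :]

    sig_names = [f"S{i + 1}" for i in range(k)]
    return SignatureSet(
        signatures=pd.DataFrame(H, index=sig_names, columns=CONTEXTS_96),
        exposures=pd.DataFrame(W, index=matrix.counts.index, columns=sig_names),
        reconstruction_error=err,
    )


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


@dataclass
class SignatureMatch:
    best: pd.DataFrame  # one row per found signature
    similarity: pd.DataFrame  # found x reference cosine matrix
    linkage: np.ndarray  # complete-linkage dendrogram of row-scaled stack
    leaf_labels: list[str]


def match_signatures(
    found: SignatureSet | pd.DataFrame,
    reference: pd.DataFrame,
) -> SignatureMatch:
    """Match extracted signatures to a named reference catalogue.

    Primary output: cosine-similarity best matches (catalogue order breaks
    ties).  Secondary: complete-linkage hierarchical clustering on the
    Euclidean distances of the row-scaled stacked signature matrix.
    """
    sigs = found.signatures if isinstance(found, SignatureSet) else found
    if reference.empty:
        raise ValueError("empty reference catalogue")
    if list(reference.columns) != CONTEXTS_96:
        raise ValueError("reference catalogue context order mismatch")
    if list(sigs.columns) != CONTEXTS_96:
        raise ValueError("found signatures context order mismatch")

    sim = pd.DataFrame(
        [
            [_cosine(sigs.loc[f].to_numpy(), reference.loc[r].to_numpy())
             for r in reference.index]
            for f in sigs.index
        ],
        index=sigs.index,
        columns=reference.index,
    )
    rows = []
    for f in sigs.index:
        scores = sim.loc[f]
        best_ref = scores.index[int(np.argmax(scores.to_numpy()))]
        rows.append({"signature": f, "match": best_ref, "cosine": float(scores[best_ref])})
    best = pd.DataFrame(rows)

    stacked = pd.concat([sigs, reference])
    scaled = stacked.sub(stacked.mean(axis=1), axis=0)
    std = stacked.std(axis=1).replace(0, 1.0)
    scaled = scaled.div(std, axis=0)
    Z = linkage(pdist(scaled.to_numpy(), metric="euclidean"), method="complete")
    return SignatureMatch(
        best=best, similarity=sim, linkage=Z, leaf_labels=list(stacked.index)
    )


# ---------------------------------------------------------------------------
# Reference catalogue
# ---------------------------------------------------------------------------

def synthetic_reference_catalogue() -> pd.DataFrame:
    """Constructed (synthetic) stand-in for a published signature catalogue.

    Four parametric processes with the qualitative shapes relevant to
    lymphoblastic leukemia panels: spontaneous deamination of methylated
    cytosine (C>T at NpCpG), APOBEC-family activity (C>G and C>T at TpCpA /
    TpCpT), a C>T-at-ApCpG-enriched process, and a flat background.
    """
    def build(weights: dict[str, float], background: float) -> np.ndarray:
        v = np.full(96, background / 96)
        for ctx, w in weights.items():
            v[CONTEXTS_96.index(ctx)] += w
        return v / v.sum()

    rows = {
        "CpG_deamination": build(
            {f"{f}[C>T]G": 0.85 / 4 for f in BASES}, background=0.15
        ),
        "APOBEC": build(
            {
                "T[C>G]A": 0.40,
                "T[C>G]T": 0.40,
                "T[C>T]A": 0.08,
                "T[C>T]T": 0.08,
            },
            background=0.04,
        ),
        "ApCpG_CtoT": build({"A[C>T]G": 0.80}, background=0.20),
        "Flat": np.full(96, 1 / 96),
    }
    return pd.DataFrame(rows.values(), index=list(rows.keys()), columns=CONTEXTS_96)


def load_reference_catalogue(path: str | Path | None = None) -> pd.DataFrame:
    """Load a 96-context reference catalogue TSV (contexts x named columns).

    With no path, the packaged synthetic catalogue is used.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "synthetic_signature_catalogue.tsv"
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != CONTEXTS_96:
        raise ValueError("catalogue rows must be the canonical 96 contexts in order")
    return frame.T.reindex(columns=CONTEXTS_96)
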