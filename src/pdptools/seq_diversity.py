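"""Diversity statistics for collections of near-clonal phage genomes.

Operates on small viral genomes (~15 kb) pre-aligned to a shared reference
coordinate system: pairwise nucleotide identity, species delineation at the
ICTV <95%-identity cut-off, per-site and windowed nucleotide diversity (pi),
per-gene diversity, and gene-synteny checking.  Substitution-only alignments
(the common case for these syntenic tectivirus-like genomes) keep all
sequences the same length; gaps ('-') and ambiguous bases ('N') are handled
by pairwise deletion throughout.

Coordinates are 0-based half-open internally; GFF3 input/output uses the
standard 1-based inclusive convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GenomeCollection",
    "GeneMap",
    "Gene",
    "VariantTable",
    "SpeciesClusters",
    "SyntenyReport",
    "pairwise_identity",
    "identity_matrix",
    "cluster_species",
    "variant_table",
    "windowed_pi",
    "per_gene_diversity",
    "check_synteny",
    "read_genome_collection",
    "write_genome_collection",
    "read_gene_map",
    "write_gene_map",
]

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


def _encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes: 0..3 = ACGT, 4 = N/other, 5 = gap."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    out[arr == ord("-")] = 5
    return out


def _decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN-", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


@dataclass
class GenomeCollection:
    """A reference sequence plus isolate sequences aligned to it.

    All sequences share one length (reference coordinates); isolate ids are
    unique and never equal to the reference id.
    """

    reference_id: str
    reference: str
    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("isolate ids must be unique")
        L = len(self.reference)
        for iso, seq in zip(self.ids, self.sequences):
            if len(seq) != L:
                raise ValueError(
                    f"sequence {iso} has length {len(seq)} != reference length {L}"
                )
        if len(self.ids) < 1:
            raise ValueError("collection must contain at least one isolate")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.reference)

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 code matrix of the isolates (reference excluded)."""
        return np.stack([_encode(s) for s in self.sequences])


@dataclass(frozen=True)
class Gene:
    """One gene in reference coordinates, stored 0-based half-open."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneMap:
    """Ordered gene annotation of the reference genome."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def order(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def overlapping_pairs(self) -> list[tuple[str, str]]:
        """Pairs of genes whose spans overlap (permitted, but flagged)."""
        out = []
        genes = sorted(self.genes, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            if b.start < a.end:
                out.append((a.gene_id, b.gene_id))
        return out


@dataclass
class VariantTable:
    """Per-reference-position allele counts over the isolates.

    ``counts`` is (L, 4) over A,C,G,T; ``coverage`` is the number of
    isolates with an unambiguous base at each position (gaps and N
    excluded).  Positions where the reference itself is gapped are dropped;
    ``positions`` maps rows back to original alignment columns.
    """

    counts: np.ndarray
    coverage: np.ndarray
    positions: np.ndarray
    n_isolates: int

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def site_pi(self) -> np.ndarray:
        """Per-site nucleotide diversity: sum_{a<b} c_a c_b / C(m, 2).

        Sites with coverage < 2 contribute 0.
        """
        m = self.coverage.astype(float)
        sum_sq = (self.counts.astype(float) ** 2).sum(axis=1)
        num = (m**2 - sum_sq) / 2.0
        denom = m * (m - 1) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = np.where(denom > 0, num / denom, 0.0)
        return pi

    def variant_sites(self) -> np.ndarray:
        """Boolean mask of sites with >= 2 distinct alleles observed."""
        return (self.counts > 0).sum(axis=1) >= 2


@dataclass
class SpeciesClusters:
    """Partition of isolates into species at an identity threshold."""

    assignments: dict[str, int]
    threshold: float
    linkage: str = "single"

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for iso, c in self.assignments.items():
            out.setdefault(c, []).append(iso)
        return out


@dataclass
class SyntenyReport:
    """Result of checking gene content and order against the reference."""

    passed: bool
    violations: list[dict]

    def to_json(self) -> str:
        return json.dumps({"passed": self.passed, "violations": self.violations}, indent=2)


# ---------------------------------------------------------------------------
# pairwise identity and species clustering
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over comparable positions.

    A position is comparable iff both sequences carry an unambiguous base
    (A/C/G/T); gaps and N are excluded (pairwise deletion).  Returns NaN if
    no position is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    ca, cb = _encode(a), _encode(b)
    comparable = (ca < 4) & (cb < 4)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        return float("nan")
    matches = int((ca[comparable] == cb[comparable]).sum())
    return 100.0 * matches / n_comp


def identity_matrix(collection: GenomeCollection) -> pd.DataFrame:
    """Symmetric percent-identity matrix over all isolate pairs.

    Diagonal is 100 by definition.
    """
    n = collection.n
    codes = collection.encoded()
    valid = codes < 4
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            n_comp = int(comp.sum())
            if n_comp == 0:
                mat[i, j] = mat[j, i] = np.nan
            else:
                m = int((codes[i][comp] == codes[j][comp]).sum())
                mat[i, j] = mat[j, i] = 100.0 * m / n_comp
    return pd.DataFrame(mat, index=collection.ids, columns=collection.ids)


def cluster_species(
    matrix: pd.DataFrame, threshold: float = 95.0, linkage: str = "single"
) -> SpeciesClusters:
    """Group isolates into species at an identity threshold.

    Default single linkage: two isolates belong to the same species iff
    they are connected by a chain of pairs with identity >= ``threshold``.
    A pair at exactly the threshold is linked — the species demarcation is
    *strictly below* the cut-off.  ``linkage="complete"`` instead requires
    every within-cluster pair to meet the threshold (scipy hierarchical
    clustering).
    """
    ids = list(matrix.index)
    values = matrix.to_numpy(dtype=float)
    n = len(ids)
    if n == 0:
        raise ValueError("empty identity matrix")
    adj = np.nan_to_num(values, nan=-np.inf) >= threshold
    np.fill_diagonal(adj, True)
    if linkage == "single":
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    elif linkage == "complete":
        from scipy.cluster.hierarchy import fcluster
        from scipy.cluster.hierarchy import linkage as _hier_linkage
        from scipy.spatial.distance import squareform

        if n == 1:
            labels = np.zeros(1, dtype=int)
        else:
            dist = 100.0 - np.nan_to_num(values, nan=-np.inf)
            np.fill_diagonal(dist, 0.0)
            Z = _hier_linkage(squareform(dist, checks=False), method="complete")
            labels = fcluster(Z, t=100.0 - threshold, criterion="distance") - 1
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    # renumber clusters in order of first appearance for stable output
    remap: dict[int, int] = {}
    assignments = {}
    for iso, lab in zip(ids, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignments[iso] = remap[lab]
    return SpeciesClusters(assignments=assignments, threshold=threshold, linkage=linkage)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def variant_table(collection: GenomeCollection) -> VariantTable:
    """Tally per-position allele counts over the isolates.

    Alignment columns where the reference is gapped are dropped so that
    windows and gene coordinates refer to the ungapped reference.
    """
    codes = collection.encoded()
    ref = _encode(collection.reference)
    keep = ref != 5
    positions = np.nonzero(keep)[0]
    codes = codes[:, keep]
    counts = np.zeros((codes.shape[1], 4), dtype=np.int64)
    for base in range(4):
        counts[:, base] = (codes == base).sum(axis=0)
    coverage = counts.sum(axis=1)
    return VariantTable(
        counts=counts,
        coverage=coverage,
        positions=positions,
        n_isolates=collection.n,
    )


def windowed_pi(table: VariantTable, window: int = 100) -> pd.DataFrame:
    """Nucleotide diversity in non-overlapping windows tiling the reference.

    Window pi is the sum of per-site pi divided by the window width (the
    vcftools convention: span, not covered-site count); a short final window
    is divided by its actual span.  Returns a frame with 0-based half-open
    ``start``/``end``, ``pi``, ``n_variant_sites`` and ``mean_coverage``.
    """
    if window < 1:
        raise ValueError("window width must be >= 1")
    site_pi = table.site_pi()
    variant = table.variant_sites()
    L = table.length
    rows = []
    for start in range(0, L, window):
        end = min(start + window, L)
        span = end - start
        rows.append(
            {
                "start": start,
                "end": end,
                "pi": float(site_pi[start:end].sum() / span),
                "n_variant_sites": int(variant[start:end].sum()),
                "mean_coverage": float(table.coverage[start:end].mean()),
            }
        )
    return pd.DataFrame(rows)


def per_gene_diversity(table: VariantTable, genes: GeneMap) -> pd.DataFrame:
    """Mean per-site pi over each gene span (strand-independent).

    The denominator is the gene length, matching the window convention.
    """
    site_pi = table.site_pi()
    L = table.length
    rows = []
    for gene in genes:
        if gene.start < 0 or gene.end > L or gene.start >= gene.end:
            raise ValueError(
                f"gene {gene.gene_id} span [{gene.start}, {gene.end}) is outside the "
                f"reference [0, {L})"
            )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "start": gene.start,
                "end": gene.end,
                "pi": float(site_pi[gene.start : gene.end].sum() / gene.length),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "pi"])


# ---------------------------------------------------------------------------
# synteny
# ---------------------------------------------------------------------------

def _longest_increasing_subsequence(seq: Sequence[int]) -> list[int]:
    """Indices of one longest strictly increasing subsequence."""
    if not seq:
        return []
    tails: list[int] = []  # index into seq of smallest tail per length
    prev = [-1] * len(seq)
    for i, x in enumerate(seq):
        lo, hi = 0, len(tails)
        while lo < hi:
            mid = (lo + hi) // 2
            if seq[tails[mid]] < x:
                lo = mid + 1
            else:
                hi = mid
        if lo > 0:
            prev[i] = tails[lo - 1]
        if lo == len(tails):
            tails.append(i)
        else:
            tails[lo] = i
    out = []
    i = tails[-1]
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def check_synteny(
    annotations: Mapping[str, Sequence[str]], reference_order: Sequence[str]
) -> SyntenyReport:
    """Check that every isolate carries exactly the reference genes in the
    reference order.

    Violations are itemized per isolate as ``missing`` (reference gene
    absent), ``extra`` (gene not in the reference), and ``out-of-order``
    (a minimal set of displaced genes — those outside a longest common
    increasing run with the reference order).
    """
    reference_order = list(reference_order)
    if not reference_order:
        raise ValueError("reference gene order is empty")
    ref_index = {g: i for i, g in enumerate(reference_order)}
    if len(ref_index) != len(reference_order):
        raise ValueError("reference gene order contains duplicates")
    violations: list[dict] = []
    for isolate, order in annotations.items():
        order = list(order)
        present = set(order)
        for g in reference_order:
            if g not in present:
                violations.append({"isolate": isolate, "kind": "missing", "gene": g})
        for g in order:
            if g not in ref_index:
                violations.append({"isolate": isolate, "kind": "extra", "gene": g})
        shared = [g for g in order if g in ref_index]
        ranks = [ref_index[g] for g in shared]
        lis = set(_longest_increasing_subsequence(ranks))
        for i, g in enumerate(shared):
            if i not in lis:
                violations.append({"isolate": isolate, "kind": "out-of-order", "gene": g})
    return SyntenyReport(passed=not violations, violations=violations)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_genome_collection(
    path: str | Path, reference_id: str = "REF"
) -> GenomeCollection:
    """Read an aligned multi-FASTA; the reference record (id ``REF`` by
    default) may appear anywhere but conventionally comes first."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ref = None
    ids, seqs = [], []
    for rec in records:
        if rec.id == reference_id:
            if ref is not None:
                raise ValueError(f"duplicate reference id {reference_id!r}")
            ref = str(rec.seq)
        else:
            ids.append(rec.id)
            seqs.append(str(rec.seq))
    if ref is None:
        raise ValueError(f"reference id {reference_id!r} not found in {path}")
    return GenomeCollection(reference_id=reference_id, reference=ref, ids=ids, sequences=seqs)


def write_genome_collection(collection: GenomeCollection, path: str | Path) -> None:
    """Write the collection as multi-FASTA with the reference first."""
    with open(path, "w") as fh:
        fh.write(f">{collection.reference_id}\n{collection.reference}\n")
        for iso, seq in zip(collection.ids, collection.sequences):
            fh.write(f">{iso}\n{seq}\n")


_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gene_map(path: str | Path) -> GeneMap:
    """Read a GFF3 gene map (1-based inclusive), keeping ``gene`` features
    (or all features if none is typed ``gene``)."""
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLUMNS, dtype=str
    )
    if (frame["type"] == "gene").any():
        frame = frame[frame["type"] == "gene"]
    genes = []
    for _, row in frame.iterrows():
        attrs = dict(
            item.split("=", 1) for item in str(row["attributes"]).split(";") if "=" in item
        )
        gene_id = attrs.get("ID") or attrs.get("Name")
        if gene_id is None:
            raise ValueError(f"GFF3 feature without ID attribute: {row.to_dict()}")
        start1, end1 = int(row["start"]), int(row["end"])
        if start1 < 1 or end1 < start1:
            raise ValueError(f"invalid GFF3 coordinates for {gene_id}: {start1}-{end1}")
        genes.append(
            Gene(gene_id=gene_id, start=start1 - 1, end=end1, strand=str(row["strand"]))
        )
    return GeneMap(genes=genes)


def write_gene_map(genes: GeneMap, path: str | Path, seqid: str = "REF") -> None:
    """Write the gene map as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{seqid}\tpdptools\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
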