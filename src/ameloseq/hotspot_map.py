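"""Cross-species transfer of cancer hotspot positions by protein alignment.

Human hotspot catalogs index residues in human protein coordinates (BRAF
V600E). The canine ortholog may differ in length — canine BRAF lacks a short
human-specific segment upstream of the kinase domain, so the same residue is
V595 — and the transfer is a residue-level correspondence computed from a
global pairwise alignment of the two protein sequences.

The aligner is a standard Needleman–Wunsch/Gotoh dynamic program with
BLOSUM62 substitution scores and affine gaps. It is written here (rather than
delegated to a library aligner) so that traceback ties are broken in a fixed,
documented order and the mapping is bit-reproducible; library aligners are
used as independent cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: default affine gap penalties (positive costs): a gap of length k costs
#: GAP_OPEN + (k-1)*GAP_EXTEND, matching common protein-alignment defaults.
GAP_OPEN = 11.0
GAP_EXTEND = 1.0

_NEG_INF = float("-inf")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class HotspotEntry:
    """One human cancer hotspot: residue position and permitted substitutions."""

    gene_symbol: str
    human_protein_pos: int
    ref_aa: str
    alt_aas: frozenset = frozenset()  # empty = any non-reference substitution

    def __post_init__(self) -> None:
        if self.human_protein_pos < 1:
            raise ValueError("human_protein_pos must be >= 1")
        if self.ref_aa not in _AA_SET:
            raise ValueError(f"invalid reference residue {self.ref_aa!r}")

    @property
    def label(self) -> str:
        return f"{self.gene_symbol}-{self.ref_aa}{self.human_protein_pos}"


@dataclass
class OrthologMap:
    """Residue-level correspondence between a human protein and its canine ortholog."""

    gene_symbol: str
    human_seq: str
    canine_seq: str
    aligned_pairs: list  # [(human_pos, canine_pos)] 1-based, non-gap columns
    alignment_score: float

    def human_to_canine(self) -> dict[int, int]:
        return {h: c for h, c in self.aligned_pairs}

    def canine_to_human(self) -> dict[int, int]:
        return {c: h for h, c in self.aligned_pairs}


@dataclass
class MappedHotspot:
    """Result of transferring one hotspot entry to canine coordinates."""

    entry: HotspotEntry
    canine_pos: Optional[int]  # None when the human residue aligns to a gap
    canine_ref_aa: Optional[str] = None
    residue_match: Optional[bool] = None  # canine residue equals catalog ref_aa


def _validate_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} protein sequence is empty")
    seq = seq.upper().rstrip("*")
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(f"{name} sequence contains invalid residues {sorted(bad)}")
    return seq


def _score(a: str, b: str) -> float:
    return float(_BLOSUM62[a][b])


def align_orthologs(
    human_seq: str,
    canine_seq: str,
    gene_symbol: str = "",
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> OrthologMap:
    """Global affine-gap alignment of two protein sequences.

    Deterministic: traceback ties are broken diagonal > up (gap in canine) >
    left (gap in human), and among end states match > up > left.
    """
    x = _validate_protein(human_seq, "human")
    y = _validate_protein(canine_seq, "canine")
    n, m = len(x), len(y)

    # three-state Gotoh: M ends in a substitution column, U ends consuming x
    # (gap in canine, "up"), L ends consuming y (gap in human, "left")
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    U = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    L = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        U[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        L[0][j] = -gap_open - (j - 1) * gap_extend

    for i in range(1, n + 1):
        xi = x[i - 1]
        row_m, row_u, row_l = M[i], U[i], L[i]
        prev_m, prev_u, prev_l = M[i - 1], U[i - 1], L[i - 1]
        for j in range(1, m + 1):
            diag = prev_m[j - 1]
            if prev_u[j - 1] > diag:
                diag = prev_u[j - 1]
            if prev_l[j - 1] > diag:
                diag = prev_l[j - 1]
            row_m[j] = diag + _score(xi, y[j - 1])

            up = prev_m[j] - gap_open
            if prev_u[j] - gap_extend > up:
                up = prev_u[j] - gap_extend
            if prev_l[j] - gap_open > up:
                up = prev_l[j] - gap_open
            row_u[j] = up

            left = row_m[j - 1] - gap_open
            if row_u[j - 1] - gap_open > left:
                left = row_u[j - 1] - gap_open
            if row_l[j - 1] - gap_extend > left:
                left = row_l[j - 1] - gap_extend
            row_l[j] = left

    # traceback; state preference order implements the documented tie-breaks
    def best_state(i: int, j: int) -> str:
        vals = {"M": M[i][j], "U": U[i][j], "L": L[i][j]}
        top = max(vals.values())
        for s in ("M", "U", "L"):
            if vals[s] == top:
                return s

    pairs: list[tuple[int, int]] = []
    i, j = n, m
    state = best_state(n, m)
    score = {"M": M, "U": U, "L": L}[state][n][m]
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i, j))
            i, j = i - 1, j - 1
            state = best_state(i, j) if (i or j) else "M"
        elif state == "U":
            target = U[i][j]
            if M[i - 1][j] - gap_open == target:
                nxt = "M"
            elif U[i - 1][j] - gap_extend == target:
                nxt = "U"
            else:
                nxt = "L"
            i, state = i - 1, nxt
        else:  # L
            target = L[i][j]
            if M[i][j - 1] - gap_open == target:
                nxt = "M"
            elif U[i][j - 1] - gap_open == target:
                nxt = "U"
            else:
                nxt = "L"
            j, state = j - 1, nxt
    pairs.reverse()
    return OrthologMap(
        gene_symbol=gene_symbol,
        human_seq=x,
        canine_seq=y,
        aligned_pairs=pairs,
        alignment_score=score,
    )


def map_hotspot(entry: HotspotEntry, omap: OrthologMap) -> MappedHotspot:
    """Transfer one human hotspot position to canine coordinates.

    Absence (the human residue falls in a gapped column) and a canine residue
    that differs from the catalog's reference are returned states, not errors:
    true inter-species reference differences exist and are flagged, not fatal.
    """
    if omap.gene_symbol and entry.gene_symbol != omap.gene_symbol:
        raise ValueError(
            f"gene mismatch: hotspot {entry.gene_symbol} vs map {omap.gene_symbol}"
        )
    canine_pos = omap.human_to_canine().get(entry.human_protein_pos)
    if canine_pos is None:
        return MappedHotspot(entry=entry, canine_pos=None)
    canine_aa = omap.canine_seq[canine_pos - 1]
    return MappedHotspot(
        entry=entry,
        canine_pos=canine_pos,
        canine_ref_aa=canine_aa,
        residue_match=(canine_aa == entry.ref_aa),
    )


def match_variant_to_hotspot(call, catalog: Iterable[HotspotEntry], maps) -> Optional[HotspotEntry]:
    """Test whether a consequence call hits a catalog hotspot at the
    orthologous canine position.

    ``maps`` is a mapping of gene symbol to :class:`OrthologMap`. A match
    requires a missense call (or stop-gain where the catalog permits '*'),
    the mapped canine position, the catalog reference residue, and a
    permitted substitution (an empty ``alt_aas`` permits any non-reference
    change). A gene absent from the catalog or maps is simply no match.
    """
    if call.klass not in ("missense", "stop_gain") or call.protein_pos is None:
        return None
    gene = call.gene_symbol
    omap = maps.get(gene)
    if omap is None:
        return None
    for entry in catalog:
        if entry.gene_symbol != gene:
            continue
        if call.klass == "stop_gain" and entry.alt_aas and "*" not in entry.alt_aas:
            continue
        mapped = map_hotspot(entry, omap)
        if mapped.canine_pos != call.protein_pos:
            continue
        if call.ref_aa != entry.ref_aa:
            continue
        if entry.alt_aas and call.klass == "missense" and call.alt_aa not in entry.alt_aas:
            continue
        call.variant.annotations["hotspot_match"] = entry.label
        return entry
    return None


def read_hotspot_catalog(path) -> list[HotspotEntry]:
    """Read a hotspot catalog TSV: gene, human_pos, ref_aa, alt_aas."""
    entries = []
    with open(path) as fh:
        header = None
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            if header is None:
                header = ln.split("\t")
                continue
            row = dict(zip(header, ln.split("\t")))
            alts = row.get("alt_aas", "").strip()
            entries.append(
                HotspotEntry(
                    gene_symbol=row["gene"].upper(),
                    human_protein_pos=int(row["human_pos"]),
                    ref_aa=row["ref_aa"].upper(),
                    alt_aas=frozenset(a for a in alts.split(",") if a),
                )
            )
    if not entries:
        raise ValueError(f"hotspot catalog {path} is empty")
    return entries


def hotspot_genomic_loci(catalog, maps, transcripts) -> set[tuple]:
    """Genomic (chrom, 1-based pos) loci of all mapped hotspot codons.

    Used by the low-VAF rescue: these are the positions a reviewer would
    manually inspect. All three bases of each mapped codon are included.
    """
    by_gene = {tx.gene_symbol: tx for tx in transcripts}
    loci: set[tuple] = set()
    for entry in catalog:
        omap = maps.get(entry.gene_symbol)
        tx = by_gene.get(entry.gene_symbol)
        if omap is None or tx is None:
            continue
        mapped = map_hotspot(entry, omap)
        if mapped.canine_pos is None or mapped.canine_pos > tx.protein_length:
            continue
        for pos in tx.codon_genomic_positions(mapped.canine_pos):
            loci.add((tx.chrom, pos))
    return loci
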