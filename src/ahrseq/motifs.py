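"""Promoter extraction and AHRE motif scanning.

The aryl hydrocarbon receptor (AhR), once ligand-activated, dimerizes with
ARNT and binds short DNA elements (AHREs, also called xenobiotic response
elements) in target-gene promoters.  This module extracts the 3,000-nt
window upstream of each transcription start site, scans both strands for
perfect matches to the three known AHRE variants, and partitions
AhR-dependent genes into canonical-eligible (at least one AHRE present)
versus non-canonical (no AHRE anywhere in the promoter).

Coordinates are 0-based half-open internally; everything read or written
follows the 1-based closed GFF3 convention.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MotifSpec",
    "MotifHit",
    "PromoterRegion",
    "GeneMotifProfile",
    "BUILTIN_MOTIFS",
    "builtin_motifs",
    "compile_motif",
    "scan",
    "revcomp",
    "extract_promoters",
    "profile_genes",
    "canonical_partition",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _parse_pattern(pattern: str) -> list[frozenset[str]]:
    """Tokenize a degenerate pattern over {A,C,G,T,n,(X/Y)} into per-position
    allowed-base sets."""
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch in "ACGT":
            positions.append(frozenset(ch))
            i += 1
        elif ch in "nN":
            positions.append(frozenset("ACGT"))
            i += 1
        elif ch == "(":
            j = pattern.index(")", i)
            alts = frozenset(pattern[i + 1 : j].split("/"))
            if not alts <= frozenset("ACGT"):
                raise ValueError(f"unknown symbol in alternation {pattern[i:j+1]!r}")
            positions.append(alts)
            i = j + 1
        else:
            raise ValueError(f"unknown symbol {ch!r} in motif pattern {pattern!r}")
    return positions


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate DNA motif; ``n`` matches any base, ``(A/T)`` either."""

    motif_id: str
    pattern: str

    @property
    def positions(self) -> list[frozenset[str]]:
        return _parse_pattern(self.pattern)

    @property
    def length(self) -> int:
        return len(self.positions)

    @property
    def cardinality(self) -> int:
        """Number of concrete sequences in the degenerate expansion."""
        n = 1
        for alts in self.positions:
            n *= len(alts)
        return n

    def concretize(self, rng) -> str:
        """One concrete member of the expansion, degenerate slots drawn
        uniformly with ``rng`` (a numpy Generator)."""
        return "".join(sorted(alts)[rng.integers(len(alts))] for alts in self.positions)


#: The three AHRE variants scanned in promoters: the core AHRE I pentamer
#: bound by the AhR-ARNT dimer, the extended AHRE II, and the RelB-associated
#: AHRE of non-canonical NF-kB/AhR signaling.
BUILTIN_MOTIFS: dict[str, MotifSpec] = {
    "AHRE_I": MotifSpec("AHRE_I", "GCGTG"),
    "AHRE_II": MotifSpec("AHRE_II", "CATGnnnnnnC(A/T)TG"),
    "RELB": MotifSpec("RELB", "GGGTGCAT"),
}


def builtin_motifs() -> list[MotifSpec]:
    return list(BUILTIN_MOTIFS.values())


class CompiledMotif:
    """Regex-backed matcher for one motif on both strands.

    Reverse-strand matching is defined as matching the reverse complement of
    the expansion against the forward sequence, so a single forward pass
    reports hits on either strand.
    """

    def __init__(self, spec: MotifSpec):
        self.spec = spec
        fwd = _parse_pattern(spec.pattern)
        rev = [frozenset(b.translate(_COMPLEMENT) for b in alts) for alts in reversed(fwd)]
        self._fwd_re = re.compile("(?=(" + self._to_regex(fwd) + "))")
        self._rev_re = re.compile("(?=(" + self._to_regex(rev) + "))")

    @staticmethod
    def _to_regex(positions: list[frozenset[str]]) -> str:
        out = []
        for alts in positions:
            if len(alts) == 1:
                out.append(next(iter(alts)))
            else:
                out.append("[" + "".join(sorted(alts)) + "]")
        return "".join(out)

    def finditer(self, sequence: str):
        """Yield (position, strand, matched_text) for every perfect match on
        either strand; overlapping matches are all reported.  matched_text is
        given 5'->3' on the strand of the match."""
        for m in self._fwd_re.finditer(sequence):
            yield m.start(), "+", m.group(1)
        for m in self._rev_re.finditer(sequence):
            yield m.start(), "-", revcomp(m.group(1))


def compile_motif(spec: MotifSpec) -> CompiledMotif:
    """Compile a :class:`MotifSpec` into a both-strand matcher."""
    return CompiledMotif(spec)


@dataclass(frozen=True)
class MotifHit:
    """A perfect motif match within a scanned sequence.

    ``position`` is the 0-based offset of the match start on the forward
    (reported) sequence; ``strand`` is the strand of the match itself.
    """

    motif_id: str
    position: int
    strand: str
    matched_text: str
    gene_id: str | None = None


def scan(
    sequence: str,
    motifs: Iterable[MotifSpec] | None = None,
    gene_id: str | None = None,
) -> list[MotifHit]:
    """Scan a sequence for perfect motif matches on both strands.

    Lowercase (soft-masked) bases are uppercased before scanning; characters
    outside A/C/G/T never match.  Hits are ordered by position, then strand
    (+ before -), then motif id.
    """
    if motifs is None:
        motifs = builtin_motifs()
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for spec in motifs:
        matcher = compile_motif(spec)
        for pos, strand, text in matcher.finditer(seq):
            hits.append(MotifHit(spec.motif_id, pos, strand, text, gene_id))
    hits.sort(key=lambda h: (h.position, h.strand != "+", h.motif_id))
    return hits


@dataclass(frozen=True)
class PromoterRegion:
    """Upstream window of a gene, reported 5'->3' toward the TSS.

    ``start``/``end`` are 1-based closed genomic coordinates of the window on
    the contig; ``sequence`` is reverse-complemented for minus-strand genes so
    that scanning is orientation-consistent (presence calls are unaffected
    because both strands are scanned).
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def promoter_interval(tss: int, strand: str, contig_length: int, window: int = 3000) -> tuple[int, int]:
    """1-based closed genomic interval of the upstream window, clipped at the
    contig boundary.  Upstream is leftward for + genes, rightward for -.
    Returns (start, end) with start > end when the window is empty."""
    if strand == "+":
        return max(1, tss - window), tss - 1
    return tss + 1, min(contig_length, tss + window)


def extract_promoters(
    genes,
    genome: Mapping[str, str],
    window: int = 3000,
) -> list[PromoterRegion]:
    """Extract the ``window``-nt upstream region of every gene.

    ``genes`` is an iterable of objects with gene_id/contig/strand/tss
    attributes (e.g. :class:`ahrseq.simulate.GeneModel`); ``genome`` maps
    contig id to sequence.  Windows are clipped at contig edges; a clipped or
    empty window triggers a warning, not an error.
    """
    promoters = []
    for gene in genes:
        if gene.contig not in genome:
            raise KeyError(f"gene {gene.gene_id}: unknown contig {gene.contig!r}")
        contig_seq = genome[gene.contig]
        if not 1 <= gene.tss <= len(contig_seq):
            raise ValueError(f"gene {gene.gene_id}: TSS {gene.tss} outside contig")
        start, end = promoter_interval(gene.tss, gene.strand, len(contig_seq), window)
        if end < start:
            warnings.warn(f"gene {gene.gene_id}: empty promoter window (TSS at contig edge)")
            seq = ""
            start, end = gene.tss, gene.tss - 1
        else:
            seq = contig_seq[start - 1 : end]
            if end - start + 1 < window:
                warnings.warn(
                    f"gene {gene.gene_id}: promoter clipped to {end - start + 1} nt at contig boundary"
                )
            if gene.strand == "-":
                seq = revcomp(seq)
        promoters.append(PromoterRegion(gene.gene_id, gene.contig, start, end, gene.strand, seq))
    return promoters


@dataclass
class GeneMotifProfile:
    """Per-gene motif hit counts and presence flags over its promoter."""

    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def present(self, motif_id: str) -> bool:
        return self.counts.get(motif_id, 0) > 0

    @property
    def any_ahre(self) -> bool:
        return any(c > 0 for c in self.counts.values())


def profile_genes(
    promoters: Sequence[PromoterRegion],
    motifs: Iterable[MotifSpec] | None = None,
) -> dict[str, GeneMotifProfile]:
    """Scan every promoter and build per-gene motif profiles.

    Returns a dict keyed by gene id.  Duplicate gene ids are an error;
    zero-length promoters yield all-zero profiles with a warning.
    """
    if motifs is None:
        motifs = builtin_motifs()
    motifs = list(motifs)
    profiles: dict[str, GeneMotifProfile] = {}
    for prom in promoters:
        if prom.gene_id in profiles:
            raise ValueError(f"duplicate gene id {prom.gene_id!r} among promoters")
        counts = {m.motif_id: 0 for m in motifs}
        if not prom.sequence:
            warnings.warn(f"gene {prom.gene_id}: zero-length promoter, all-zero motif profile")
        else:
            for hit in scan(prom.sequence, motifs, gene_id=prom.gene_id):
                counts[hit.motif_id] += 1
        profiles[prom.gene_id] = GeneMotifProfile(prom.gene_id, counts)
    return profiles


def profiles_to_frame(profiles: Mapping[str, GeneMotifProfile]) -> pd.DataFrame:
    """Tabular view of profiles: one row per gene, count and presence per
    motif plus the any_ahre flag."""
    rows = []
    for gene_id, prof in profiles.items():
        row: dict = {"gene_id": gene_id}
        for motif_id, count in prof.counts.items():
            row[f"n_{motif_id}"] = count
            row[f"has_{motif_id}"] = count > 0
        row["any_ahre"] = prof.any_ahre
        rows.append(row)
    return pd.DataFrame(rows)


def canonical_partition(
    dependency_calls: pd.DataFrame,
    profiles: Mapping[str, GeneMotifProfile],
    motifs: Iterable[MotifSpec] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Partition AhR-dependent genes into canonical-eligible vs non-canonical.

    ``dependency_calls`` needs columns gene_id/ligand/time/label.  For each
    (ligand, time) cell the returned table gives, among that cell's
    AhR-dependent genes, the count and proportion possessing each motif and
    the count lacking all of them.  The second return value is the sorted
    union of non-canonical (no AHRE at all) dependent gene ids.

    The absence of an AHRE definitively excludes canonical AhR-ARNT
    regulation; presence only makes it possible.
    """
    if motifs is None:
        motifs = builtin_motifs()
    motif_ids = [m.motif_id for m in motifs]
    dep = dependency_calls[dependency_calls["label"] == "ahr_dependent"]
    missing = set(dep["gene_id"]) - set(profiles)
    if missing:
        raise KeyError(f"dependent genes missing from motif profiles: {sorted(missing)[:5]}...")
    rows = []
    noncanonical: set[str] = set()
    for (ligand, time), cell in dep.groupby(["ligand", "time"], sort=True):
        genes = sorted(set(cell["gene_id"]))
        n = len(genes)
        row: dict = {"ligand": ligand, "time": time, "n_dependent": n}
        for mid in motif_ids:
            k = sum(profiles[g].present(mid) for g in genes)
            row[f"n_{mid}"] = k
            row[f"frac_{mid}"] = k / n if n else 0.0
        non = [g for g in genes if not profiles[g].any_ahre]
        row["n_any_ahre"] = n - len(non)
        row["frac_any_ahre"] = (n - len(non)) / n if n else 0.0
        row["n_noncanonical"] = len(non)
        noncanonical.update(non)
        rows.append(row)
    return pd.DataFrame(rows), sorted(noncanonical)
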