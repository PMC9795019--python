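"""Small-RNA tag catalog: length filtering, collapsing, and mapping.

Collapsed sequencing tags (18-26 nt after filtering) are mapped ungapped
against a mature miRNA reference, a precursor reference, and the genome.
The resulting per-tag boolean evidence drives the five-group miRNA
classification in :mod:`peonymir.mirna_discovery`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

GENOTYPES = ("FD", "MU", "LH")
STAGES = ("BS", "IF", "FB", "DE")

MIN_TAG_LEN = 18
MAX_TAG_LEN = 26

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")

# byte -> 2-bit base code; anything non-ACGT maps to 4 and never matches
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet (T)."""
    return seq.strip().upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class LibraryDesign:
    """One sequencing library: genotype x developmental stage x replicate."""

    genotype: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def label(self) -> str:
        return f"{self.genotype}_{self.stage}_{self.replicate}"


def default_design(n_replicates: int = 3) -> list[LibraryDesign]:
    """3 genotypes x 4 stages x n replicates, in fixed column order."""
    return [
        LibraryDesign(g, s, r)
        for g in GENOTYPES
        for s in STAGES
        for r in range(1, n_replicates + 1)
    ]


@dataclass(frozen=True)
class GenomeHit:
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class MappingEvidence:
    """Aggregated mapping facts for one tag, consumed by the classifier."""

    tag: str
    hits_mature_ref: bool
    mature_hit_id: str | None
    mature_mismatches: int | None
    mature_hit_ids: tuple[str, ...]
    hits_precursor_ref: bool
    precursor_hit_id: str | None
    precursor_maps_genome: bool
    tag_maps_genome: bool
    genome_loci: tuple[GenomeHit, ...]

    def __post_init__(self) -> None:
        if self.tag_maps_genome != bool(self.genome_loci):
            raise ValueError("genome_loci must be non-empty iff tag_maps_genome")


def hamming_scan(query: np.ndarray, subject: np.ndarray, max_mismatches: int):
    """All ungapped alignments of *query* within *subject*.

    Returns [(0-based offset, mismatch count), ...] for every window with at
    most *max_mismatches* mismatches.
    """
    L = len(query)
    if L == 0 or len(subject) < L:
        return []
    windows = sliding_window_view(subject, L)
    mm = (windows != query).sum(axis=1)
    hits = np.nonzero(mm <= max_mismatches)[0]
    return [(int(i), int(mm[i])) for i in hits]


class GenomeIndex:
    """Pre-encoded contigs supporting brute-force Hamming mapping.

    Instances are cheap for desk-scale genomes; mapping is exhaustive so all
    tied occurrences are reported.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("empty reference: no contigs")
        self.contigs = {name: normalize_seq(seq) for name, seq in contigs.items()}
        self._enc = {name: encode(seq) for name, seq in self.contigs.items()}

    def map_tag(
        self, tag: str, max_mismatches: int = 0, both_strands: bool = True
    ) -> list[GenomeHit]:
        tag = normalize_seq(tag)
        fwd = encode(tag)
        rev = encode(revcomp(tag))
        hits: list[GenomeHit] = []
        for name in self.contigs:
            subject = self._enc[name]
            for off, mm in hamming_scan(fwd, subject, max_mismatches):
                hits.append(GenomeHit(name, off + 1, off + len(tag), "+", mm))
            if both_strands:
                for off, mm in hamming_scan(rev, subject, max_mismatches):
                    hits.append(GenomeHit(name, off + 1, off + len(tag), "-", mm))
        return hits

    def fetch(self, contig: str, start: int, end: int) -> str:
        """1-based inclusive slice, truncated at contig bounds."""
        seq = self.contigs[contig]
        return seq[max(start - 1, 0) : min(end, len(seq))]


def map_to_reference(
    tag: str, reference: Mapping[str, str], max_mismatches: int = 0
) -> list[tuple[str, int]]:
    """Forward-strand ungapped hits of *tag* inside reference records.

    Returns [(record id, best mismatch count), ...] sorted by mismatches then
    id, so the first element is the best hit.
    """
    if not reference:
        raise ValueError("empty reference")
    tag = normalize_seq(tag)
    q = encode(tag)
    out: list[tuple[str, int]] = []
    for rec_id, seq in reference.items():
        scans = hamming_scan(q, encode(normalize_seq(seq)), max_mismatches)
        if scans:
            out.append((rec_id, min(mm for _, mm in scans)))
    out.sort(key=lambda h: (h[1], h[0]))
    return out


def filter_and_collapse(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Length-filter and collapse a raw tag table.

    *raw* must have a ``sequence`` column plus one integer count column per
    library. Tags outside 18-26 nt or with non-ACGT/U characters are
    rejected; duplicate sequences are merged by summing counts. Returns
    ``(catalog, rejected)`` where *catalog* is indexed by normalized
    sequence and *rejected* carries a ``reason`` column. Kept and rejected
    rows partition the input.
    """
    if "sequence" not in raw.columns:
        raise ValueError("raw tag table needs a 'sequence' column")
    count_cols = [c for c in raw.columns if c != "sequence"]
    seqs = raw["sequence"].map(normalize_seq)
    valid_alphabet = seqs.str.fullmatch("[ACGT]+").fillna(False)
    lengths = seqs.str.len()
    in_range = (lengths >= MIN_TAG_LEN) & (lengths <= MAX_TAG_LEN)

    keep = valid_alphabet & in_range
    reasons = pd.Series("", index=raw.index, dtype=object)
    reasons[~valid_alphabet] = "non-alphabet character"
    reasons[valid_alphabet & ~in_range] = "length outside 18-26 nt"

    rejected = raw.loc[~keep].copy()
    rejected["reason"] = reasons[~keep]

    kept = raw.loc[keep, count_cols].copy()
    kept.index = seqs[keep]
    catalog = kept.groupby(level=0, sort=True).sum()
    catalog.index.name = "sequence"
    logger.info(
        "filter_and_collapse: kept %d/%d rows (%d unique tags), rejected %d",
        int(keep.sum()),
        len(raw),
        len(catalog),
        int((~keep).sum()),
    )
    return catalog, rejected


def collect_evidence(
    sequences: Iterable[str],
    mature_ref: Mapping[str, str],
    precursor_ref: Mapping[str, str],
    genome: GenomeIndex,
    max_mismatches_ref: int = 2,
    max_mismatches_genome: int = 0,
) -> list[MappingEvidence]:
    """Compute one :class:`MappingEvidence` per tag.

    Mature-reference assignment tolerates up to *max_mismatches_ref* ungapped
    mismatches (forward strand only); genome and precursor-to-genome mapping
    are exact by default. ``precursor_maps_genome`` is true if the precursor
    of ANY mature hit maps to the genome.
    """
    precursor_on_genome = {
        pid: bool(genome.map_tag(seq, max_mismatches_genome))
        for pid, seq in precursor_ref.items()
    }
    evidence = []
    for seq in sequences:
        seq = normalize_seq(seq)
        mature_hits = (
            map_to_reference(seq, mature_ref, max_mismatches_ref) if mature_ref else []
        )
        prec_hits = (
            map_to_reference(seq, precursor_ref, max_mismatches_ref)
            if precursor_ref
            else []
        )
        loci = tuple(genome.map_tag(seq, max_mismatches_genome))
        prec_maps = any(
            precursor_on_genome.get(hit_id, False) for hit_id, _ in mature_hits
        )
        evidence.append(
            MappingEvidence(
                tag=seq,
                hits_mature_ref=bool(mature_hits),
                mature_hit_id=mature_hits[0][0] if mature_hits else None,
                mature_mismatches=mature_hits[0][1] if mature_hits else None,
                mature_hit_ids=tuple(h for h, _ in mature_hits),
                hits_precursor_ref=bool(prec_hits),
                precursor_hit_id=prec_hits[0][0] if prec_hits else None,
                precursor_maps_genome=prec_maps,
                tag_maps_genome=bool(loci),
                genome_loci=loci,
            )
        )
    return evidence


def evidence_table(evidence: Sequence[MappingEvidence]) -> pd.DataFrame:
    """Flatten evidence records into a TSV-friendly table."""
    rows = []
    for ev in evidence:
        rows.append(
            {
                "sequence": ev.tag,
                "hits_mature_ref": ev.hits_mature_ref,
                "mature_hit_id": ev.mature_hit_id or "",
                "mature_mismatches": (
                    ev.mature_mismatches if ev.mature_mismatches is not None else -1
                ),
                "hits_precursor_ref": ev.hits_precursor_ref,
                "precursor_hit_id": ev.precursor_hit_id or "",
                "precursor_maps_genome": ev.precursor_maps_genome,
                "tag_maps_genome": ev.tag_maps_genome,
                "genome_loci": ";".join(
                    f"{h.contig}:{h.start}-{h.end}({h.strand})" for h in ev.genome_loci
                ),
            }
        )
    return pd.DataFrame(rows)
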