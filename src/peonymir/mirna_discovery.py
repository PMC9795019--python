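"""Hairpin (fold-back) testing and five-group miRNA classification.

A genomic locus carrying a candidate mature miRNA is accepted as a MIR
locus when the mature arm forms a stem-loop duplex with one of its flanks:
at least ``min_paired`` mature positions paired (Watson-Crick or G:U
wobble), no bulge larger than ``max_bulge`` nt, and a terminal loop of at
least ``min_loop`` nt, with the mature fully on one arm. The duplex is
found by a small glocal alignment (global in the mature, local in the
flank) rather than thermodynamic folding.

Tags are then assigned to one of five groups by mapping evidence:

- gp1:  hits the mature reference and the reference precursor maps to the
        genome (known miRNA with a conserved locus);
- gp2a: hits the mature reference, precursor absent from the genome, but
        the tag maps to a genomic locus whose extension folds back;
- gp2b: as gp2a but no genomic locus of the tag can form a hairpin;
- gp3:  hits the mature reference but does not map to the genome at all;
- gp4:  no reference hit, maps to the genome, and some locus folds back
        (novel/predicted miRNA).

Anything else is UNCLASSIFIED and is not a miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .smallrna_catalog import GenomeHit, GenomeIndex, MappingEvidence, revcomp

GROUPS = ("gp1", "gp2a", "gp2b", "gp3", "gp4")
UNCLASSIFIED = "UNCLASSIFIED"

DEFAULT_FLANK = 120
DEFAULT_MIN_PAIRED = 16
DEFAULT_MAX_BULGE = 3
DEFAULT_MIN_LOOP = 3

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass
class HairpinStats:
    paired_mature: int
    largest_bulge: int
    loop_size: int


@dataclass
class Hairpin:
    contig: str
    start: int
    end: int
    strand: str
    precursor_seq: str
    pairing: str  # dot-bracket, same length as precursor_seq
    mature_arm: str  # '5p' or '3p'
    mature_offset: int  # 0-based offset of mature within precursor_seq
    stats: HairpinStats


@dataclass
class FoldBackResult:
    accepted: bool
    hairpin: Hairpin | None
    reason: str | None  # failed criterion when rejected


@dataclass
class MiRNARecord:
    id: str
    sequence: str
    group: str  # gp1..gp4 or UNCLASSIFIED
    known: bool
    precursor: Hairpin | None
    evidence: MappingEvidence

    def __post_init__(self) -> None:
        if self.group in ("gp1", "gp2a", "gp4") and self.precursor is None:
            raise ValueError(f"{self.group} record requires a precursor hairpin")
        if self.group in ("gp2b", "gp3") and self.precursor is not None:
            raise ValueError(f"{self.group} record must not carry a precursor")


def _duplex_align(mature: str, flank: str):
    """Glocal duplex alignment of the mature arm against one flank.

    The flank is reversed so that antiparallel pairing becomes positional:
    match requires base complementarity (WC or G:U). Gaps model bulges.
    Returns (paired, largest_bulge, flank_positions_paired, aligned_pairs)
    where flank positions are 0-based offsets into the original flank and
    aligned_pairs is [(mature_idx | None, flank_idx | None), ...] over the
    aligned core.
    """
    m = mature
    r = flank[::-1]
    L, F = len(m), len(r)
    if F == 0:
        return 0, 0, [], []
    MATCH, MISMATCH, GAP = 3.0, -2.0, -3.0
    NEG = -1e18
    dp = np.full((L + 1, F + 1), NEG)
    ptr = np.zeros((L + 1, F + 1), dtype=np.int8)  # 1=diag 2=up(gap in flank) 3=left
    dp[0, :] = 0.0  # free leading flank
    for i in range(1, L + 1):
        dp[i, 0] = dp[i - 1, 0] + GAP
        ptr[i, 0] = 2
    for i in range(1, L + 1):
        mi = m[i - 1]
        for j in range(1, F + 1):
            diag = dp[i - 1, j - 1] + (MATCH if (mi, r[j - 1]) in _PAIRS else MISMATCH)
            up = dp[i - 1, j] + GAP
            left = dp[i, j - 1] + GAP
            best = diag
            p = 1
            if up > best:
                best, p = up, 2
            if left > best:
                best, p = left, 3
            dp[i, j] = best
            ptr[i, j] = p
    j = int(np.argmax(dp[L, :]))
    i = L
    pairs: list[tuple[int | None, int | None]] = []
    while i > 0:
        p = ptr[i, j]
        if p == 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif p == 2:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()

    paired = 0
    flank_paired: list[int] = []
    paired_flags = []
    for mi, fj in pairs:
        ok = (
            mi is not None
            and fj is not None
            and (m[mi], r[fj]) in _PAIRS
        )
        paired_flags.append(mi is not None and fj is not None and ok)
        if ok:
            paired += 1
            flank_paired.append(F - 1 - fj)  # back to original flank coords

    # largest bulge: longest gap run strictly inside the paired core
    largest_bulge = 0
    if flank_paired:
        idx_paired = [k for k, (mi, fj) in enumerate(pairs) if paired_flags[k]]
        lo, hi = idx_paired[0], idx_paired[-1]
        run = 0
        for k in range(lo, hi + 1):
            mi, fj = pairs[k]
            if mi is None or fj is None:
                run += 1
                largest_bulge = max(largest_bulge, run)
            else:
                run = 0
    return paired, largest_bulge, flank_paired, pairs


def fold_back(
    genome: GenomeIndex,
    locus: GenomeHit | tuple[str, int, int, str],
    flank: int = DEFAULT_FLANK,
    min_paired: int = DEFAULT_MIN_PAIRED,
    max_bulge: int = DEFAULT_MAX_BULGE,
    min_loop: int = DEFAULT_MIN_LOOP,
) -> FoldBackResult:
    """Test whether the extended sequence at *locus* folds back into a hairpin.

    The locus (1-based inclusive) names the mature arm; *flank* nt are added
    on each side (truncated at contig ends) and the better of the two
    flank duplexes decides acceptance. Rejections name the failed criterion.
    """
    if isinstance(locus, tuple):
        locus = GenomeHit(*locus, mismatches=0)
    contig_seq = genome.contigs.get(locus.contig)
    if contig_seq is None:
        raise ValueError(f"unknown contig {locus.contig!r}")
    if locus.start < 1 or locus.end > len(contig_seq) or locus.start > locus.end:
        raise ValueError(f"locus {locus} outside contig bounds")

    win_start = max(locus.start - flank, 1)
    win_end = min(locus.end + flank, len(contig_seq))
    window = genome.fetch(locus.contig, win_start, win_end)
    up_len = locus.start - win_start
    mature_len = locus.end - locus.start + 1
    if locus.strand == "-":
        window = revcomp(window)
        up_len = win_end - locus.end
    mature = window[up_len : up_len + mature_len]
    upstream = window[:up_len]
    downstream = window[up_len + mature_len :]

    best: tuple | None = None
    for side, fl in (("down", downstream), ("up", upstream)):
        paired, bulge, flank_paired, pairs = _duplex_align(mature, fl)
        if not flank_paired:
            loop = -1
        elif side == "down":
            loop = min(flank_paired)  # nt between mature 3' end and duplex
        else:
            loop = len(fl) - 1 - max(flank_paired)
        cand = (paired, -bulge, side, fl, flank_paired, pairs, bulge, loop)
        if best is None or cand[:2] > best[:2]:
            best = cand

    paired, _, side, fl, flank_paired, pairs, bulge, loop = best
    if paired < min_paired:
        return FoldBackResult(False, None, f"paired {paired} < {min_paired}")
    if bulge > max_bulge:
        return FoldBackResult(False, None, f"bulge {bulge} > {max_bulge}")
    if loop < min_loop:
        return FoldBackResult(False, None, f"loop {loop} < {min_loop}")

    # assemble precursor sequence + dot-bracket in 5'->3' order
    lo_f, hi_f = min(flank_paired), max(flank_paired)
    mature_paired = {
        mi for mi, fj in pairs if mi is not None and fj is not None
        and (mature[mi], fl[::-1][fj]) in _PAIRS
    }
    flank_set = set(flank_paired)
    if side == "down":
        arm_seq = fl[: hi_f + 1]
        precursor = mature + arm_seq
        brackets = "".join(
            "(" if i in mature_paired else "." for i in range(len(mature))
        ) + "".join(")" if k in flank_set else "." for k in range(len(arm_seq)))
        mature_arm, mature_offset = "5p", 0
    else:
        arm_seq = fl[lo_f:]
        precursor = arm_seq + mature
        brackets = "".join(
            "(" if (lo_f + k) in flank_set else "." for k in range(len(arm_seq))
        ) + "".join(")" if i in mature_paired else "." for i in range(len(mature)))
        mature_arm, mature_offset = "3p", len(arm_seq)

    hairpin = Hairpin(
        contig=locus.contig,
        start=locus.start,
        end=locus.end,
        strand=locus.strand,
        precursor_seq=precursor,
        pairing=brackets,
        mature_arm=mature_arm,
        mature_offset=mature_offset,
        stats=HairpinStats(paired_mature=paired, largest_bulge=bulge, loop_size=loop),
    )
    return FoldBackResult(True, hairpin, None)


def classify(
    evidence: MappingEvidence,
    genome: GenomeIndex,
    record_id: str,
    flank: int = DEFAULT_FLANK,
    min_paired: int = DEFAULT_MIN_PAIRED,
    max_bulge: int = DEFAULT_MAX_BULGE,
    min_loop: int = DEFAULT_MIN_LOOP,
) -> MiRNARecord:
    """Assign exactly one group by the first matching rule.

    Branch order: gp1, gp2a, gp2b, gp3, gp4, else UNCLASSIFIED. Multi-locus
    tags use existential ("some locus folds back") semantics.
    """

    def any_accepting_hairpin() -> Hairpin | None:
        for locus in evidence.genome_loci:
            res = fold_back(genome, locus, flank, min_paired, max_bulge, min_loop)
            if res.accepted:
                return res.hairpin
        return None

    hairpin: Hairpin | None = None
    if evidence.hits_mature_ref:
        if evidence.precursor_maps_genome:
            group = "gp1"
            hairpin = any_accepting_hairpin()
        elif evidence.tag_maps_genome:
            hairpin = any_accepting_hairpin()
            group = "gp2a" if hairpin is not None else "gp2b"
        else:
            group = "gp3"
    else:
        if evidence.tag_maps_genome:
            hairpin = any_accepting_hairpin()
            group = "gp4" if hairpin is not None else UNCLASSIFIED
        else:
            group = UNCLASSIFIED

    if group in ("gp2b", "gp3", UNCLASSIFIED):
        hairpin = None
    return MiRNARecord(
        id=record_id,
        sequence=evidence.tag,
        group=group,
        known=group in ("gp1", "gp2a", "gp2b", "gp3"),
        precursor=hairpin,
        evidence=evidence,
    )


def classify_catalog(
    evidence: Sequence[MappingEvidence],
    genome: GenomeIndex,
    **fold_params,
) -> list[MiRNARecord]:
    """Classify every tag; known records are named after their best reference
    hit, novel (gp4) records get sequential PC- identifiers."""
    records = []
    novel_n = 0
    unclass_n = 0
    seen: dict[str, int] = {}
    for ev in evidence:
        rec = classify(ev, genome, record_id="", **fold_params)
        if rec.group == "gp4":
            novel_n += 1
            rec.id = f"PC-{novel_n:04d}"
        elif rec.group == UNCLASSIFIED:
            unclass_n += 1
            rec.id = f"TAG-{unclass_n:04d}"
        else:
            base = ev.mature_hit_id or "mir-unknown"
            seen[base] = seen.get(base, 0) + 1
            rec.id = base if seen[base] == 1 else f"{base}_{seen[base]}"
        records.append(rec)
    return records


def summarize_groups(records: Iterable[MiRNARecord]) -> pd.DataFrame:
    """Group summary table: precursor-level and mature-level counts.

    ``unique_mirna`` counts unique mature sequences per group;
    ``pre_mirna`` counts distinct precursor identities (reference precursor
    id for known groups, accepted hairpin locus for gp4; for gp2b/gp3,
    which have no genomic precursor, the distinct reference ids hit). The
    known total is the sum of the gp1-gp3 rows.
    """
    per_group_seqs: dict[str, set] = {g: set() for g in GROUPS}
    per_group_prec: dict[str, set] = {g: set() for g in GROUPS}
    for rec in records:
        if rec.group == UNCLASSIFIED:
            continue
        per_group_seqs[rec.group].add(rec.sequence)
        if rec.group == "gp4":
            hp = rec.precursor
            per_group_prec[rec.group].add((hp.contig, hp.start, hp.end, hp.strand))
        else:
            per_group_prec[rec.group].add(rec.evidence.mature_hit_id)

    rows = []
    for g in GROUPS:
        rows.append(
            {"group": g, "pre_mirna": len(per_group_prec[g]),
             "unique_mirna": len(per_group_seqs[g])}
        )
    df = pd.DataFrame(rows).set_index("group")
    known = df.loc[["gp1", "gp2a", "gp2b", "gp3"]].sum()
    predicted = df.loc[["gp4"]].sum()
    df.loc["known_total"] = known
    df.loc["predicted_total"] = predicted
    df.loc["total"] = known + predicted
    return df.astype(int)


def records_table(records: Sequence[MiRNARecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        hp = rec.precursor
        rows.append(
            {
                "id": rec.id,
                "sequence": rec.sequence,
                "group": rec.group,
                "known": rec.known,
                "locus": (
                    f"{hp.contig}:{hp.start}-{hp.end}({hp.strand})" if hp else ""
                ),
                "precursor": hp.precursor_seq if hp else "",
                "structure": hp.pairing if hp else "",
            }
        )
    return pd.DataFrame(rows)
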