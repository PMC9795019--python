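"""miRNA target prediction and degradome-based cleavage validation.

Targets are found by an exhaustive complementarity scan of every
transcript window against the miRNA (antiparallel). Each position
contributes a penalty: 0 for a Watson-Crick pair, 0.5 for a G:U wobble,
1.0 for a mismatch, doubled over miRNA positions 2-13 (the functionally
critical 5' region). Sites at or below ``max_penalty`` (default 2.5) are
reported with their expected slicer cleavage coordinate: the transcript
base paired with miRNA position 10, since AGO-catalysed cleavage falls
between the bases opposite miRNA positions 10 and 11.

Degradome libraries record the 5' ends of uncapped transcripts; a count
peak at the expected cleavage position of a predicted site is evidence of
miRNA-guided slicing. Validated sites carry a t-plot category:

0  peak equals the transcript maximum and the maximum is unique
1  peak equals the transcript maximum, shared with other positions
2  peak above the transcript positional mean but below the maximum
3  peak > 1 but at or below the mean
4  peak is a single raw count
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .smallrna_catalog import encode, normalize_seq, revcomp

logger = logging.getLogger(__name__)

DEFAULT_MAX_PENALTY = 2.5
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
CORE_START, CORE_END = 2, 13  # 1-based miRNA positions with doubled costs
CORE_WEIGHT = 2.0
CLEAVAGE_MIRNA_POS = 10


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive on transcript
    end: int
    penalty: float
    alignment: str  # per miRNA position 5'->3': '|' WC, 'o' G:U, 'x' mismatch
    cleavage_pos: int  # transcript coordinate paired with miRNA position 10


@dataclass
class DegradomeProfile:
    transcript_id: str
    counts: np.ndarray  # per 1-based position; index 0 <-> position 1
    library: str

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ValidatedCleavage:
    site: TargetSite
    library: str
    peak_pos: int
    peak_count: int
    transcript_max: int
    category: int


def _position_weights(length: int) -> np.ndarray:
    w = np.ones(length)
    core = slice(CORE_START - 1, min(CORE_END, length))
    w[core] = CORE_WEIGHT
    return w


def _penalty_table(mirna: str) -> np.ndarray:
    """(L, 4) per-position cost of each target base, miRNA 5'->3'."""
    wc = {"A": "T", "C": "G", "G": "C", "T": "A"}
    wobble = {"G": "T", "T": "G"}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(mirna)
    tab = np.full((L, 4), MISMATCH_PENALTY)
    for i, m in enumerate(mirna):
        tab[i, base_idx[wc[m]]] = 0.0
        if m in wobble:
            tab[i, base_idx[wobble[m]]] = WOBBLE_PENALTY
    return tab * _position_weights(L)[:, None]


def predict_targets(
    mirna_id: str,
    mirna_seq: str,
    transcripts: dict[str, str],
    max_penalty: float = DEFAULT_MAX_PENALTY,
) -> list[TargetSite]:
    """Scan every transcript window of miRNA length; report sites with
    penalty <= max_penalty. A miRNA longer than a transcript yields no
    sites for that transcript."""
    mirna = normalize_seq(mirna_seq)
    L = len(mirna)
    tab = _penalty_table(mirna)
    weights = _position_weights(L)
    # window position j pairs miRNA position L-j (antiparallel)
    tab_by_window = tab[::-1]
    weights_by_window = weights[::-1]
    pos_idx = np.arange(L)
    sites: list[TargetSite] = []
    for tid, tseq in transcripts.items():
        tseq = normalize_seq(tseq)
        if len(tseq) < L:
            continue
        enc = encode(tseq)
        windows = sliding_window_view(enc, L)  # (n_windows, L)
        valid = windows < 4
        costs = tab_by_window[pos_idx[None, :], np.minimum(windows, 3)]
        costs = np.where(valid, costs, MISMATCH_PENALTY * weights_by_window)
        penalties = costs.sum(axis=1)
        for j0 in np.nonzero(penalties <= max_penalty)[0]:
            start = int(j0) + 1
            end = start + L - 1
            window = tseq[j0 : j0 + L]
            align = []
            for i in range(L):  # miRNA position i+1 pairs window index L-1-i
                t = window[L - 1 - i]
                raw = (
                    tab[i, "ACGT".index(t)] / weights[i]
                    if t in "ACGT"
                    else MISMATCH_PENALTY
                )
                align.append("|" if raw == 0 else ("o" if raw == WOBBLE_PENALTY else "x"))
            sites.append(
                TargetSite(
                    mirna_id=mirna_id,
                    transcript_id=tid,
                    start=start,
                    end=end,
                    penalty=float(penalties[j0]),
                    alignment="".join(align),
                    cleavage_pos=end - (CLEAVAGE_MIRNA_POS - 1),
                )
            )
    return sites


def build_profiles(
    degradome: pd.DataFrame,
    transcript_lengths: dict[str, int],
    library: str,
) -> dict[str, DegradomeProfile]:
    """Accumulate 5'-end counts per transcript position.

    *degradome* needs columns transcript_id, position (1-based), count.
    Out-of-bounds records are skipped with a logged warning; transcripts
    absent from the table get all-zero profiles on demand via
    :func:`profile_for`.
    """
    profiles: dict[str, DegradomeProfile] = {}
    skipped = 0
    for row in degradome.itertuples(index=False):
        tid, pos, count = row.transcript_id, int(row.position), int(row.count)
        length = transcript_lengths.get(tid)
        if length is None or not (1 <= pos <= length):
            skipped += 1
            continue
        if tid not in profiles:
            profiles[tid] = DegradomeProfile(tid, np.zeros(length, dtype=np.int64), library)
        profiles[tid].counts[pos - 1] += count
    if skipped:
        logger.warning("build_profiles[%s]: skipped %d out-of-bounds records", library, skipped)
    return profiles


def profile_for(
    profiles: dict[str, DegradomeProfile],
    transcript_id: str,
    transcript_lengths: dict[str, int],
    library: str,
) -> DegradomeProfile:
    prof = profiles.get(transcript_id)
    if prof is None:
        prof = DegradomeProfile(
            transcript_id,
            np.zeros(transcript_lengths[transcript_id], dtype=np.int64),
            library,
        )
    return prof


def categorize(peak_count: int, counts: np.ndarray) -> int:
    """t-plot category of a peak within its transcript profile."""
    if peak_count == 1:
        return 4
    tmax = int(counts.max())
    mean = float(counts.mean())
    if peak_count == tmax:
        return 0 if int((counts == tmax).sum()) == 1 else 1
    if peak_count > mean:
        return 2
    return 3


def validate_cleavage(
    site: TargetSite,
    profile: DegradomeProfile,
    window: int = 1,
) -> ValidatedCleavage | None:
    """Cross-reference a predicted site against a degradome profile.

    The peak is the max-count position within +/-window nt of the expected
    cleavage coordinate; returns None when that peak has zero counts.
    """
    counts = profile.counts
    lo = max(site.cleavage_pos - window, 1)
    hi = min(site.cleavage_pos + window, len(counts))
    if lo > hi:
        return None
    segment = counts[lo - 1 : hi]
    peak_count = int(segment.max())
    if peak_count == 0:
        return None
    peak_pos = lo + int(segment.argmax())
    return ValidatedCleavage(
        site=site,
        library=profile.library,
        peak_pos=peak_pos,
        peak_count=peak_count,
        transcript_max=int(counts.max()),
        category=categorize(peak_count, counts),
    )


def sites_table(sites: list[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "penalty": s.penalty,
                "alignment": s.alignment,
                "cleavage_pos": s.cleavage_pos,
            }
            for s in sites
        ],
        columns=[
            "mirna_id", "transcript_id", "start", "end",
            "penalty", "alignment", "cleavage_pos",
        ],
    )
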