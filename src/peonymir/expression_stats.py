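"""Count normalization and differential-expression calling.

DEMs (differentially expressed miRNAs) are called per feature by a one-way
ANOVA F-test on log2(CPM+1), significant at P <= alpha (the boundary is
inclusive for DEMs). DEGs (genes) are called per pairwise contrast by a
joint rule: fold change > 2 or < 0.5 AND Welch-t P < 0.05 (strict).
Contrast labels follow the "FD:DEvsBS" (stage pair within genotype) and
"BS:LHvsFD" (genotype pair within stage) convention; the part before "vs"
is the numerator (B) of the fold change.

No multiple-testing correction is applied by default, matching the raw-P
criteria; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .smallrna_catalog import GENOTYPES, STAGES

DEM_ALPHA_TIERS = (0.01, 0.05, 0.1)


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: raw[i,j] / colsum(j) * 1e6.

    Raises if any library has a zero total (naming it); preserves
    within-library rank order of features.
    """
    colsums = counts.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"zero-total library: {', '.join(map(str, zero.index))}")
    return counts / colsums * 1e6


def fpkm(fragments, mapped_reads, exon_length_nt):
    """Fragments per kilobase of exon per million mapped reads.

    fragments / (mapped_reads/1e6 * exon_length/1e3). Scalar or array.
    """
    mapped_reads = np.asarray(mapped_reads, dtype=float)
    exon_length_nt = np.asarray(exon_length_nt, dtype=float)
    if np.any(mapped_reads <= 0):
        raise ValueError("mapped_reads must be positive")
    if np.any(exon_length_nt <= 0):
        raise ValueError("exon_length must be positive")
    out = np.asarray(fragments, dtype=float) / (
        mapped_reads / 1e6 * exon_length_nt / 1e3
    )
    return float(out) if out.ndim == 0 else out


def fpkm_matrix(counts: pd.DataFrame, exon_lengths: pd.Series) -> pd.DataFrame:
    """Per-library FPKM for a count matrix (features x libraries)."""
    lengths = exon_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index[:3].tolist()
        raise ValueError(f"missing exon length for features {missing}")
    mapped = counts.sum(axis=0)
    return counts / (mapped / 1e6) / (lengths.to_numpy()[:, None] / 1e3)


def _anova_f(groups: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA across features (rows).

    Each element of *groups* is (n_features, n_replicates). Returns (F, p);
    features with zero between- and within-group variance get F=0, p=1.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    ns = [g.shape[1] for g in groups]
    if min(ns) < 2:
        raise ValueError("ANOVA needs >= 2 replicates per group")
    N = sum(ns)
    means = [g.mean(axis=1) for g in groups]
    grand = sum(g.sum(axis=1) for g in groups) / N
    ssb = sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    ssw = sum(((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means))
    dfb, dfw = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(F, dfb, dfw)
    # degenerate features: all values identical -> no evidence (p=1);
    # zero within-group variance but real group differences -> p -> 0
    const = (ssb <= 1e-12) & (ssw <= 1e-12)
    sep = (ssw <= 1e-12) & (ssb > 1e-12)
    F = np.where(const, 0.0, F)
    p = np.where(const, 1.0, np.where(sep, 0.0, p))
    return F, p


def dem_anova(
    normalized: pd.DataFrame,
    group_labels: Mapping[str, str],
    alpha_tiers: Sequence[float] = DEM_ALPHA_TIERS,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """ANOVA DEM test on log2(normalized+1).

    *group_labels* maps library column -> group name. Returns a frame with
    F, p, and one boolean ``sig_<alpha>`` column per tier (P <= alpha,
    inclusive). Tier flags are nested by construction.
    """
    groups: dict[str, list[str]] = {}
    for lib, grp in group_labels.items():
        groups.setdefault(grp, []).append(lib)
    logged = np.log2(normalized + 1.0)
    arrays = [logged[libs].to_numpy() for libs in groups.values()]
    F, p = _anova_f(arrays)
    if bh_correct:
        p = _benjamini_hochberg(p)
    out = pd.DataFrame({"F": F, "p": p}, index=normalized.index)
    for a in alpha_tiers:
        out[f"sig_{a}"] = out["p"] <= a
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def dem_pairwise(
    normalized: pd.DataFrame,
    libs_a: Sequence[str],
    libs_b: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group DEM comparison with the same ANOVA machinery.

    With two groups the F-test equals the squared equal-variance t-test.
    Direction is the sign of the B-vs-A log2 fold change (on log2(CPM+1)
    means) when significant at P <= alpha, else 'none'.
    """
    logged = np.log2(normalized + 1.0)
    a = logged[list(libs_a)].to_numpy()
    b = logged[list(libs_b)].to_numpy()
    F, p = _anova_f([a, b])
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    sig = p <= alpha
    direction = np.where(~sig, "none", np.where(log2fc > 0, "up", "down"))
    out = pd.DataFrame(
        {"F": F, "p": p, "log2fc": log2fc, "significant": sig, "direction": direction},
        index=normalized.index,
    )
    return out


def deg_call(
    normalized: pd.DataFrame,
    libs_a: Sequence[str],
    libs_b: Sequence[str],
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Joint fold-change + Welch-t DEG rule for the contrast B vs A.

    fold change = (mean_B + pseudocount) / (mean_A + pseudocount) on the
    normalized scale; P from Welch's t on log2(normalized+1); significant
    iff (FC > fc_up or FC < fc_down) and P < alpha (strict).
    """
    libs_a, libs_b = list(libs_a), list(libs_b)
    missing = [c for c in libs_a + libs_b if c not in normalized.columns]
    if missing:
        raise ValueError(f"contrast group libraries missing: {missing}")
    if len(libs_a) < 2 or len(libs_b) < 2:
        raise ValueError("both contrast groups need >= 2 replicates")
    a = normalized[libs_a].to_numpy()
    b = normalized[libs_b].to_numpy()
    fc = (b.mean(axis=1) + pseudocount) / (a.mean(axis=1) + pseudocount)
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.asarray(t.pvalue)
    # zero variance in both groups: identical means -> p=1, else p -> 0
    nan = np.isnan(p)
    p = np.where(nan & np.isclose(lb.mean(axis=1), la.mean(axis=1)), 1.0, p)
    p = np.where(np.isnan(p), 0.0, p)
    passes_fc = (fc > fc_up) | (fc < fc_down)
    sig = passes_fc & (p < alpha)
    direction = np.where(
        sig & (fc > fc_up), "up", np.where(sig & (fc < fc_down), "down", "none")
    )
    return pd.DataFrame(
        {
            "fold_change": fc,
            "log2fc": np.log2(fc),
            "p": p,
            "significant": sig,
            "direction": direction,
        },
        index=normalized.index,
    )


# ---------------------------------------------------------------------------
# contrast bookkeeping

def stage_pair_contrasts() -> list[tuple[str, str, str, str]]:
    """(label, genotype, stage_B, stage_A) for every later-vs-earlier stage
    pair within each genotype, e.g. ('FD:DEvsBS', 'FD', 'DE', 'BS')."""
    out = []
    for g in GENOTYPES:
        for ai, a in enumerate(STAGES):
            for b in STAGES[ai + 1 :]:
                out.append((f"{g}:{b}vs{a}", g, b, a))
    return out


def genotype_pair_contrasts() -> list[tuple[str, str, str, str]]:
    """(label, stage, genotype_B, genotype_A) for every genotype pair within
    each stage, e.g. ('BS:LHvsFD', 'BS', 'LH', 'FD')."""
    out = []
    for s in STAGES:
        for ai, a in enumerate(GENOTYPES):
            for b in GENOTYPES[ai + 1 :]:
                out.append((f"{s}:{b}vs{a}", s, b, a))
    return out


def contrast_family(label: str) -> str:
    """'developmental' for stage-pair-within-genotype contrasts,
    'varietal' for genotype-pair-within-stage contrasts."""
    prefix = label.split(":", 1)[0]
    if prefix in GENOTYPES:
        return "developmental"
    if prefix in STAGES:
        return "varietal"
    raise ValueError(f"unrecognized contrast label {label!r}")


def libraries_for(columns: Iterable[str], genotype: str | None = None,
                  stage: str | None = None) -> list[str]:
    """Select library columns (named like FD_BS_1) by genotype and/or stage."""
    out = []
    for c in columns:
        g, s, _ = c.split("_")
        if (genotype is None or g == genotype) and (stage is None or s == stage):
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# set algebra over DE feature-id collections

def intersect_all(sets: Iterable[set]) -> set:
    sets = list(sets)
    if not sets:
        return set()
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def union_all(sets: Iterable[set]) -> set:
    out: set = set()
    for s in sets:
        out |= s
    return out


def exclusive_to(target: set, others: Iterable[set]) -> set:
    """Members of *target* absent from every other set."""
    return target - union_all(others)
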