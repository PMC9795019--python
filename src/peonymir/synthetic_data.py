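"""Synthetic multi-omics data with planted ground truth.

Generates every input the pipeline consumes — a small genome with planted
MIR loci, a miRBase-like mature/precursor reference, collapsed small-RNA
tag counts and mRNA counts for the 3-genotype x 4-stage x 3-replicate
design, per-genotype pooled degradome tags, transcript sequences and a TF
annotation — together with a machine-readable truth sidecar, so that
every downstream stage can be tested for exact recovery without any
download.

Construction guarantees per classification group:

- gp1: the full precursor hairpin is written into the genome and into the
  precursor reference;
- gp2a: a hairpin cassette (mature + loop + reverse complement) is written
  into the genome, but the reference precursor is a different, genome-
  absent sequence;
- gp2b: the mature is written into the genome with flanks rejection-
  shuffled until the fold-back test FAILS;
- gp3: the mature appears only in the reference, never in the genome;
- gp4: a genomic hairpin cassette with no reference record at all.

Counts are negative binomial with mean mu * 2^effect in affected design
cells. "Developmental" effects act at stage DE in all three genotypes (so
genotype contrasts stay null), "varietal" effects in genotype LH at all
four stages, and "dual" effects in the single cell (LH, DE); this keeps
the three evidence classes exactly recoverable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mirna_discovery
from .smallrna_catalog import (
    GENOTYPES,
    STAGES,
    GenomeHit,
    GenomeIndex,
    LibraryDesign,
    default_design,
    revcomp,
)

TF_FAMILIES = ("MYB-related", "bHLH", "Trihelix", "NAC", "GRAS", "HD-ZIP")
_BASES = np.array(list("ACGT"))

HAIRPIN_GROUPS = ("gp1", "gp2a", "gp4")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset. The seed fully
    determines every emitted file."""

    seed: int = 0
    n_contigs: int = 6
    contig_length: int = 8000
    n_planted_mir: dict = field(
        default_factory=lambda: {"gp1": 10, "gp2a": 10, "gp2b": 10, "gp3": 10, "gp4": 10}
    )
    mature_length: int = 21
    loop_length: int = 12
    n_decoy_tags: int = 180
    decoy_out_of_range_fraction: float = 0.1
    n_transcripts: int = 300
    transcript_length_range: tuple[int, int] = (800, 2400)
    design: list[LibraryDesign] = field(default_factory=default_design)
    effect_log2fc: float = 2.0
    dispersion: float = 0.05
    mean_count: float = 100.0
    n_planted_modules: int = 12
    n_extra_de_mirnas: int = 6
    n_extra_de_genes: int = 10
    degradome_peak_fraction: float = 0.9
    degradome_cleaved_tags: int = 60
    degradome_background_lambda: float = 2.0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.mean_count <= 0:
            raise ValueError("mean_count must be > 0")
        if not (0 < self.degradome_peak_fraction <= 1):
            raise ValueError("degradome_peak_fraction must be in (0, 1]")
        reps: dict[tuple[str, str], int] = {}
        for lib in self.design:
            reps[(lib.genotype, lib.stage)] = reps.get((lib.genotype, lib.stage), 0) + 1
        if reps and min(reps.values()) < 2:
            raise ValueError("design needs >= 2 replicates per genotype x stage cell")
        labels = [lib.label for lib in self.design]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate libraries in design")

    @property
    def library_labels(self) -> list[str]:
        return [lib.label for lib in self.design]


@dataclass
class PlantedMiRNA:
    id: str
    sequence: str  # DNA alphabet
    group: str
    locus: tuple[str, int, int, str] | None  # None for gp3


@dataclass
class PlantedModule:
    mirna_id: str
    transcript_id: str
    tf_family: str | None
    kind: str  # developmental | varietal | dual


@dataclass
class SyntheticTruth:
    planted_mirnas: list[PlantedMiRNA] = field(default_factory=list)
    # (feature id, contrast label, signed log2 effect); miRNA features are
    # keyed by tag sequence, gene features by transcript id
    planted_de_features: list[tuple[str, str, float]] = field(default_factory=list)
    # feature id -> {(genotype, stage): log2 effect} driving count means
    effect_cells: dict = field(default_factory=dict)
    planted_cleavage_sites: list[tuple[str, str, int]] = field(default_factory=list)
    planted_modules: list[PlantedModule] = field(default_factory=list)

    def mirna_by_id(self) -> dict[str, PlantedMiRNA]:
        return {m.id: m for m in self.planted_mirnas}


class GenerationError(RuntimeError):
    pass


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named sub-streams so each emitted file has stable randomness."""
    names = ["genome", "mirbase", "transcripts", "modules",
             "srna", "mrna", "degradome"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _occurs(genome: dict[str, str], seq: str) -> bool:
    rc = revcomp(seq)
    return any(seq in contig or rc in contig for contig in genome.values())


# ---------------------------------------------------------------------------
# genome

def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[dict], SyntheticTruth]:
    """Random contigs with planted MIR loci.

    Returns (contigs, GFF-like locus rows, truth-with-planted-miRNAs).
    Hairpin-group loci are verified to pass the fold-back oracle at
    generation time; gp2b flanks are rejection-shuffled until it fails.
    """
    rng = rng or _rngs(config.seed)["genome"]
    contigs = {
        f"contig{c + 1}": list(_random_seq(rng, config.contig_length))
        for c in range(config.n_contigs)
    }
    names = list(contigs)
    L = config.mature_length
    cassette_len = 2 * L + config.loop_length

    # non-overlapping slots, spaced so gp2b flank shuffles stay disjoint
    spacing = 400
    slots = [
        (name, pos)
        for name in names
        for pos in range(300, config.contig_length - spacing, spacing)
    ]
    order = rng.permutation(len(slots))
    slot_iter = iter(order)

    truth = SyntheticTruth()
    gff_rows: list[dict] = []
    matures: set[str] = set()

    def draw_mature(current: dict[str, str]) -> str:
        for _ in range(config.max_attempts):
            m = _random_seq(rng, L)
            if m not in matures and not _occurs(current, m):
                matures.add(m)
                return m
        raise GenerationError("could not draw a genome-absent mature sequence")

    def as_strings() -> dict[str, str]:
        return {n: "".join(s) for n, s in contigs.items()}

    for group in ("gp1", "gp2a", "gp2b", "gp4"):
        for i in range(config.n_planted_mir.get(group, 0)):
            mid = f"pmir-{group}-{i + 1:02d}"
            mature = draw_mature(as_strings())
            name, pos = slots[next(slot_iter)]
            locus = (name, pos + 1, pos + L, "+")
            if group in HAIRPIN_GROUPS:
                ok = False
                for _ in range(config.max_attempts):
                    loop = _random_seq(rng, config.loop_length)
                    cassette = mature + loop + revcomp(mature)
                    contigs[name][pos : pos + cassette_len] = list(cassette)
                    res = mirna_discovery.fold_back(GenomeIndex(as_strings()),
                                                    GenomeHit(*locus, 0))
                    if res.accepted:
                        ok = True
                        break
                if not ok:
                    raise GenerationError(f"no accepting hairpin for locus {mid}")
            else:  # gp2b: mature embedded, flanks shuffled until fold-back fails
                contigs[name][pos : pos + L] = list(mature)
                ok = False
                for _ in range(config.max_attempts):
                    res = mirna_discovery.fold_back(GenomeIndex(as_strings()),
                                                    GenomeHit(*locus, 0))
                    if not res.accepted:
                        ok = True
                        break
                    flank = 120
                    lo = max(pos - flank, 0)
                    contigs[name][lo:pos] = list(_random_seq(rng, pos - lo))
                    hi = min(pos + L + flank, config.contig_length)
                    contigs[name][pos + L : hi] = list(_random_seq(rng, hi - pos - L))
                if not ok:
                    raise GenerationError(
                        f"flank shuffling failed to break hairpin at locus {mid}"
                    )
            truth.planted_mirnas.append(PlantedMiRNA(mid, mature, group, locus))
            gff_rows.append(
                {
                    "seqid": name, "source": "peonymir", "type": "miRNA",
                    "start": locus[1], "end": locus[2], "score": ".",
                    "strand": "+", "phase": ".",
                    "attributes": f"ID={mid};group={group}",
                }
            )

    final = as_strings()
    for i in range(config.n_planted_mir.get("gp3", 0)):
        mid = f"pmir-gp3-{i + 1:02d}"
        mature = draw_mature(final)
        truth.planted_mirnas.append(PlantedMiRNA(mid, mature, "gp3", None))

    return final, gff_rows, truth


# ---------------------------------------------------------------------------
# reference

def simulate_mirbase(
    config: SimulationConfig,
    truth: SyntheticTruth,
    genome: dict[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Mature + precursor reference FASTA contents.

    gp1 precursors are the exact genomic hairpin; gp2a/gp2b/gp3 precursors
    are genome-absent synthetic contexts; gp4 appears in neither file.
    """
    rng = rng or _rngs(config.seed)["mirbase"]
    mature_ref: dict[str, str] = {}
    precursor_ref: dict[str, str] = {}
    cassette_len = 2 * config.mature_length + config.loop_length
    for m in truth.planted_mirnas:
        if m.group == "gp4":
            continue
        mature_ref[m.id] = m.sequence
        if m.group == "gp1":
            contig, start, _, _ = m.locus
            precursor_ref[m.id] = genome[contig][start - 1 : start - 1 + cassette_len]
        else:
            for _ in range(config.max_attempts):
                prec = _random_seq(rng, 25) + m.sequence + _random_seq(rng, 25)
                if not _occurs(genome, prec):
                    precursor_ref[m.id] = prec
                    break
            else:
                raise GenerationError(f"could not build genome-absent precursor for {m.id}")
    return mature_ref, precursor_ref


# ---------------------------------------------------------------------------
# transcripts, modules, effects

def simulate_transcripts(
    config: SimulationConfig,
    truth: SyntheticTruth,
    rng_transcripts: np.random.Generator | None = None,
    rng_modules: np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Transcript sequences plus TF annotation; plants module target sites
    and cleavage positions, and assigns all DE effects into the truth."""
    rngs = None
    if rng_transcripts is None or rng_modules is None:
        rngs = _rngs(config.seed)
    rng_t = rng_transcripts or rngs["transcripts"]
    rng_m = rng_modules or rngs["modules"]

    lo, hi = config.transcript_length_range
    transcripts = {
        f"T{i + 1:04d}": _random_seq(rng_t, int(rng_t.integers(lo, hi + 1)))
        for i in range(config.n_transcripts)
    }
    tids = list(transcripts)

    n_mod = config.n_planted_modules
    n_dual = n_mod // 6
    n_dev = (n_mod - n_dual + 1) // 2
    n_var = n_mod - n_dual - n_dev
    kinds = ["developmental"] * n_dev + ["varietal"] * n_var + ["dual"] * n_dual

    mirnas = list(truth.planted_mirnas)
    if n_mod + config.n_extra_de_mirnas > len(mirnas):
        raise GenerationError("not enough planted miRNAs for requested modules")
    mir_pick = rng_m.permutation(len(mirnas))
    target_pick = rng_m.permutation(len(tids))

    tf_annotation: dict[str, str] = {}
    n_tf = (2 * n_mod + 2) // 3  # about two thirds of modules are TF-targeting
    eff = config.effect_log2fc

    def add_effect(feature: str, cells: list[tuple[str, str]],
                   contrasts: list[str], log2fc: float) -> None:
        cellmap = truth.effect_cells.setdefault(feature, {})
        for cell in cells:
            cellmap[cell] = cellmap.get(cell, 0.0) + log2fc
        for c in contrasts:
            truth.planted_de_features.append((feature, c, log2fc))

    def cells_and_contrasts(kind: str) -> tuple[list, list]:
        if kind == "developmental":
            return ([(g, "DE") for g in GENOTYPES],
                    [f"{g}:DEvsBS" for g in GENOTYPES])
        if kind == "varietal":
            return ([("LH", s) for s in STAGES],
                    [f"{s}:LHvsFD" for s in STAGES])
        return ([("LH", "DE")], ["LH:DEvsBS", "DE:LHvsFD"])

    for i, kind in enumerate(kinds):
        mir = mirnas[mir_pick[i]]
        tid = tids[target_pick[i]]
        seq = transcripts[tid]
        site_start0 = len(seq) // 3
        rc = revcomp(mir.sequence)
        seq = seq[:site_start0] + rc + seq[site_start0 + len(rc):]
        transcripts[tid] = seq
        site_end1 = site_start0 + len(rc)  # 1-based inclusive end
        cleavage_pos = site_end1 - 9  # transcript base paired to miRNA pos 10
        truth.planted_cleavage_sites.append((mir.id, tid, cleavage_pos))

        family = TF_FAMILIES[i % len(TF_FAMILIES)] if i < n_tf else None
        if family:
            tf_annotation[tid] = family
        truth.planted_modules.append(PlantedModule(mir.id, tid, family, kind))

        sign = 1.0 if i % 2 == 0 else -1.0
        cells, contrasts = cells_and_contrasts(kind)
        add_effect(mir.sequence, cells, contrasts, sign * eff)
        add_effect(tid, cells, contrasts, -sign * eff)

    # extra (non-module) DE features to enrich the DEM/DEG sets
    for j in range(config.n_extra_de_mirnas):
        mir = mirnas[mir_pick[n_mod + j]]
        kind = "developmental" if j % 2 == 0 else "varietal"
        sign = 1.0 if j % 2 == 0 else -1.0
        cells, contrasts = cells_and_contrasts(kind)
        add_effect(mir.sequence, cells, contrasts, sign * eff)
    for j in range(config.n_extra_de_genes):
        tid = tids[target_pick[n_mod + j]]
        kind = "varietal" if j % 2 == 0 else "developmental"
        sign = 1.0 if j % 2 == 0 else -1.0
        cells, contrasts = cells_and_contrasts(kind)
        add_effect(tid, cells, contrasts, sign * eff)

    # background TF annotation on some non-module transcripts
    n_bg = config.n_transcripts // 10
    for k in range(n_bg):
        tid = tids[target_pick[-(k + 1)]]
        if tid not in tf_annotation:
            tf_annotation[tid] = TF_FAMILIES[int(rng_m.integers(len(TF_FAMILIES)))]

    return transcripts, tf_annotation


# ---------------------------------------------------------------------------
# counts

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _mean_matrix(
    features: list[str],
    base_means: np.ndarray,
    config: SimulationConfig,
    truth: SyntheticTruth,
) -> np.ndarray:
    means = np.tile(base_means[:, None], (1, len(config.design)))
    cell_of = [(lib.genotype, lib.stage) for lib in config.design]
    for i, fid in enumerate(features):
        cells = truth.effect_cells.get(fid)
        if not cells:
            continue
        for j, cell in enumerate(cell_of):
            if cell in cells:
                means[i, j] *= 2.0 ** cells[cell]
    return means


def simulate_counts(
    config: SimulationConfig,
    truth: SyntheticTruth,
    transcripts: dict[str, str],
    rng_srna: np.random.Generator | None = None,
    rng_mrna: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Raw sRNA tag table, mRNA count table, and exon lengths.

    Planted tags keep lengths in [18, 26]; a configured fraction of decoy
    tags falls outside the range to exercise the filter.
    """
    rngs = None
    if rng_srna is None or rng_mrna is None:
        rngs = _rngs(config.seed)
    rng_s = rng_srna or rngs["srna"]
    rng_g = rng_mrna or rngs["mrna"]
    labels = config.library_labels

    planted_seqs = [m.sequence for m in truth.planted_mirnas]
    seen = set(planted_seqs)
    n_oor = int(round(config.n_decoy_tags * config.decoy_out_of_range_fraction))
    decoys: list[str] = []
    for k in range(config.n_decoy_tags):
        if k < n_oor:
            length = int(rng_s.choice([15, 16, 17, 27, 28, 29, 30]))
        else:
            length = int(rng_s.integers(18, 27))
        for _ in range(config.max_attempts):
            s = _random_seq(rng_s, length)
            if s not in seen:
                seen.add(s)
                decoys.append(s)
                break
        else:
            raise GenerationError("could not draw a unique decoy tag")

    srna_features = planted_seqs + decoys
    base = np.concatenate(
        [
            np.full(len(planted_seqs), config.mean_count),
            rng_s.lognormal(np.log(config.mean_count), 1.0, size=len(decoys)),
        ]
    )
    means = _mean_matrix(srna_features, base, config, truth)
    srna = pd.DataFrame(
        _nb_draw(rng_s, means, config.dispersion), columns=labels
    )
    srna.insert(0, "sequence", srna_features)

    tids = list(transcripts)
    has_effect = np.array([t in truth.effect_cells for t in tids])
    base_g = rng_g.lognormal(np.log(config.mean_count), 1.0, size=len(tids))
    base_g[has_effect] = config.mean_count
    means_g = _mean_matrix(tids, base_g, config, truth)
    mrna = pd.DataFrame(
        _nb_draw(rng_g, means_g, config.dispersion), columns=labels, index=tids
    )
    mrna.index.name = "transcript_id"
    lengths = pd.Series({t: len(s) for t, s in transcripts.items()}, name="exon_length")
    lengths.index.name = "transcript_id"
    return srna, mrna, lengths


def simulate_null_matrix(
    n_features: int = 2000,
    n_groups: int = 4,
    n_replicates: int = 3,
    mean_count: float = 100.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pure-null NB count matrix (no planted effects) for type-I checks.

    Returns (counts, column->group labels)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cols = [
        f"g{i + 1}_r{j + 1}" for i in range(n_groups) for j in range(n_replicates)
    ]
    counts = _nb_draw(
        rng, np.full((n_features, len(cols)), float(mean_count)), dispersion
    )
    df = pd.DataFrame(counts, columns=cols)
    return df, {c: c.split("_")[0] for c in cols}


# ---------------------------------------------------------------------------
# degradome

def simulate_degradome(
    config: SimulationConfig,
    truth: SyntheticTruth,
    transcripts: dict[str, str],
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """One 5'-end tag table per genotype (stages pooled).

    Planted cleavage positions receive >= peak_fraction of the cleaved
    transcript's tags; transcripts without a planted site get sparse
    uniform background (single-count tags).
    """
    rng = rng or _rngs(config.seed)["degradome"]
    cleaved = {tid: pos for _, tid, pos in truth.planted_cleavage_sites}
    out: dict[str, pd.DataFrame] = {}
    for genotype in GENOTYPES:
        counts: dict[tuple[str, int], int] = {}
        for tid, seq in transcripts.items():
            length = len(seq)
            if tid in cleaved:
                pos = cleaved[tid]
                if not (1 <= pos <= length):
                    raise GenerationError(
                        f"planted cleavage position {pos} outside {tid} (len {length})"
                    )
                total = config.degradome_cleaved_tags
                peak = int(np.ceil(config.degradome_peak_fraction * total))
                counts[(tid, pos)] = counts.get((tid, pos), 0) + peak
                for p in rng.integers(1, length + 1, size=total - peak):
                    counts[(tid, int(p))] = counts.get((tid, int(p)), 0) + 1
            else:
                n_bg = int(rng.poisson(config.degradome_background_lambda))
                for p in rng.integers(1, length + 1, size=n_bg):
                    counts[(tid, int(p))] = counts.get((tid, int(p)), 0) + 1
        rows = [
            {"transcript_id": tid, "position": pos, "count": c}
            for (tid, pos), c in sorted(counts.items())
        ]
        out[genotype] = pd.DataFrame(rows, columns=["transcript_id", "position", "count"])
    return out


# ---------------------------------------------------------------------------
# file emission

def _write_fasta(path: Path, records: dict[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _truth_to_jsonable(truth: SyntheticTruth) -> dict:
    return {
        "planted_mirnas": [dataclasses.asdict(m) for m in truth.planted_mirnas],
        "planted_de_features": [list(t) for t in truth.planted_de_features],
        "effect_cells": {
            fid: {f"{g}:{s}": v for (g, s), v in cells.items()}
            for fid, cells in truth.effect_cells.items()
        },
        "planted_cleavage_sites": [list(t) for t in truth.planted_cleavage_sites],
        "planted_modules": [dataclasses.asdict(m) for m in truth.planted_modules],
    }


def truth_from_json(data: dict) -> SyntheticTruth:
    truth = SyntheticTruth()
    for m in data["planted_mirnas"]:
        locus = tuple(m["locus"]) if m["locus"] else None
        truth.planted_mirnas.append(
            PlantedMiRNA(m["id"], m["sequence"], m["group"], locus)
        )
    truth.planted_de_features = [tuple(t) for t in data["planted_de_features"]]
    truth.effect_cells = {
        fid: {tuple(k.split(":")): v for k, v in cells.items()}
        for fid, cells in data["effect_cells"].items()
    }
    truth.planted_cleavage_sites = [tuple(t) for t in data["planted_cleavage_sites"]]
    truth.planted_modules = [
        PlantedModule(m["mirna_id"], m["transcript_id"], m["tf_family"], m["kind"])
        for m in data["planted_modules"]
    ]
    return truth


def simulate_all(config: SimulationConfig, outdir) -> SyntheticTruth:
    """Run every generator and write the full input bundle to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = _rngs(config.seed)

    genome, gff_rows, truth = simulate_genome(config, rngs["genome"])
    mature_ref, precursor_ref = simulate_mirbase(config, truth, genome, rngs["mirbase"])
    transcripts, tf_annotation = simulate_transcripts(
        config, truth, rngs["transcripts"], rngs["modules"]
    )
    srna, mrna, lengths = simulate_counts(
        config, truth, transcripts, rngs["srna"], rngs["mrna"]
    )
    degradome = simulate_degradome(config, truth, transcripts, rngs["degradome"])

    _write_fasta(outdir / "genome.fasta", genome)
    _write_fasta(outdir / "mature_ref.fasta", mature_ref)
    _write_fasta(outdir / "precursor_ref.fasta", precursor_ref)
    _write_fasta(outdir / "transcripts.fasta", transcripts)

    with open(outdir / "mir_loci.gff3", "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for r in gff_rows:
            fh.write(
                "\t".join(
                    str(r[k])
                    for k in ("seqid", "source", "type", "start", "end",
                              "score", "strand", "phase", "attributes")
                )
                + "\n"
            )

    srna.to_csv(outdir / "srna_counts.tsv", sep="\t", index=False, lineterminator="\n")
    mrna.to_csv(outdir / "mrna_counts.tsv", sep="\t", lineterminator="\n")
    info = pd.DataFrame(
        {
            "transcript_id": list(transcripts),
            "exon_length": [len(transcripts[t]) for t in transcripts],
            "tf_family": [tf_annotation.get(t, "") for t in transcripts],
        }
    )
    info.to_csv(outdir / "transcript_info.tsv", sep="\t", index=False, lineterminator="\n")
    for genotype, df in degradome.items():
        df.to_csv(
            outdir / f"degradome_{genotype}.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
    with open(outdir / "truth.json", "w", newline="\n") as fh:
        json.dump(_truth_to_jsonable(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth


def audit_outputs(outdir) -> list[str]:
    """Cross-file truth-consistency audit; returns a list of problems
    (empty when every planted component is present where it should be)."""
    outdir = Path(outdir)
    problems: list[str] = []
    truth = truth_from_json(json.loads((outdir / "truth.json").read_text()))
    genome = read_fasta(outdir / "genome.fasta")
    mature_ref = read_fasta(outdir / "mature_ref.fasta")
    precursor_ref = read_fasta(outdir / "precursor_ref.fasta")
    transcripts = read_fasta(outdir / "transcripts.fasta")
    srna = pd.read_csv(outdir / "srna_counts.tsv", sep="\t")
    tag_set = set(srna["sequence"])

    for m in truth.planted_mirnas:
        if m.sequence not in tag_set:
            problems.append(f"{m.id}: mature absent from sRNA table")
        in_ref = m.id in mature_ref
        if m.group == "gp4" and (in_ref or m.id in precursor_ref):
            problems.append(f"{m.id}: gp4 must be reference-absent")
        if m.group != "gp4" and not in_ref:
            problems.append(f"{m.id}: known miRNA missing from mature reference")
        if m.group == "gp3" and _occurs(genome, m.sequence):
            problems.append(f"{m.id}: gp3 mature found in genome")
        if m.locus is not None:
            contig, start, end, strand = m.locus
            if genome[contig][start - 1 : end] != m.sequence:
                problems.append(f"{m.id}: genome locus does not carry the mature")

    degradome = {
        g: pd.read_csv(outdir / f"degradome_{g}.tsv", sep="\t") for g in GENOTYPES
    }
    mir_by_id = truth.mirna_by_id()
    for mirna_id, tid, pos in truth.planted_cleavage_sites:
        if tid not in transcripts:
            problems.append(f"cleavage target {tid} missing from transcripts")
            continue
        site = transcripts[tid].find(revcomp(mir_by_id[mirna_id].sequence))
        if site < 0:
            problems.append(f"{mirna_id}->{tid}: target site not embedded")
        for g, df in degradome.items():
            hit = df[(df["transcript_id"] == tid) & (df["position"] == pos)]
            if hit.empty:
                problems.append(f"{mirna_id}->{tid}: no degradome tag at {pos} in {g}")

    module_pairs = {(m.mirna_id, m.transcript_id) for m in truth.planted_modules}
    cleaved_pairs = {(a, b) for a, b, _ in truth.planted_cleavage_sites}
    for pair in module_pairs - cleaved_pairs:
        problems.append(f"module {pair} lacks a planted cleavage site")
    for m in truth.planted_modules:
        mseq = mir_by_id[m.mirna_id].sequence
        m_contrasts = {c for f, c, _ in truth.planted_de_features if f == mseq}
        t_contrasts = {c for f, c, _ in truth.planted_de_features if f == m.transcript_id}
        shared = m_contrasts & t_contrasts
        opposite = any(
            np.sign(e1) != np.sign(e2)
            for f1, c1, e1 in truth.planted_de_features
            for f2, c2, e2 in truth.planted_de_features
            if f1 == mseq and f2 == m.transcript_id and c1 == c2
        )
        if not shared or not opposite:
            problems.append(
                f"module {m.mirna_id}->{m.transcript_id}: no opposite-signed "
                "shared planted contrast"
            )
    return problems
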