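"""End-to-end pipeline orchestration with deterministic re-runs.

Stages: simulate -> catalog -> discover -> de -> degradome -> integrate
(-> qpcr when a Ct table is configured). Every stage is a pure function of
(config, input files); the run manifest records a config hash and sha256
digests of all inputs and outputs so identical runs are provably
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from pathlib import Path

import pandas as pd
import yaml

from . import (
    expression_stats as es,
    mirna_discovery as md,
    module_integration as mi,
    qpcr_quant as qq,
    smallrna_catalog as sc,
    synthetic_data as sd,
    target_degradome as td,
)
from .smallrna_catalog import GENOTYPES, STAGES

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "catalog", "discover", "de", "degradome", "integrate", "qpcr"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # SimulationConfig field overrides
    "catalog": {"max_mismatches_ref": 2, "max_mismatches_genome": 0},
    "discover": {
        "flank": md.DEFAULT_FLANK,
        "min_paired": md.DEFAULT_MIN_PAIRED,
        "max_bulge": md.DEFAULT_MAX_BULGE,
        "min_loop": md.DEFAULT_MIN_LOOP,
    },
    "de": {
        "dem_alpha": 0.05,
        "deg_alpha": 0.05,
        "fc_up": 2.0,
        "fc_down": 0.5,
        "pseudocount": 1.0,
    },
    "degradome": {"max_penalty": td.DEFAULT_MAX_PENALTY, "window": 1},
    "qpcr": {"ct_table": None, "calibrator": None},
}


def load_config(path=None, seed: int | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if seed is not None:
        cfg["seed"] = seed
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _read_fasta_checked(path: Path) -> dict[str, str]:
    try:
        records = sd.read_fasta(path)
    except Exception as exc:  # noqa: BLE001 - surface the failing file
        raise RuntimeError(f"could not parse FASTA {path}: {exc}") from exc
    if not records:
        raise RuntimeError(f"corrupt or empty FASTA: {path}")
    return records


_LOCUS_RE = re.compile(r"([^:;]+):(\d+)-(\d+)\(([+-])\)")


def _parse_loci(spec: str) -> tuple[sc.GenomeHit, ...]:
    hits = []
    for m in _LOCUS_RE.finditer(spec or ""):
        hits.append(sc.GenomeHit(m.group(1), int(m.group(2)), int(m.group(3)),
                                 m.group(4), 0))
    return tuple(hits)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    sim_cfg = sd.SimulationConfig(seed=cfg["seed"], **cfg.get("simulate", {}))
    sd.simulate_all(sim_cfg, outdir)
    return sorted(outdir.glob("*.fasta")) + sorted(outdir.glob("*.tsv")) + [
        outdir / "mir_loci.gff3", outdir / "truth.json",
    ]


def stage_catalog(cfg: dict, outdir: Path) -> list[Path]:
    raw = pd.read_csv(outdir / "srna_counts.tsv", sep="\t")
    genome = sc.GenomeIndex(_read_fasta_checked(outdir / "genome.fasta"))
    mature_ref = _read_fasta_checked(outdir / "mature_ref.fasta")
    precursor_ref = _read_fasta_checked(outdir / "precursor_ref.fasta")
    catalog, rejected = sc.filter_and_collapse(raw)
    ev = sc.collect_evidence(
        catalog.index,
        mature_ref,
        precursor_ref,
        genome,
        max_mismatches_ref=cfg["catalog"]["max_mismatches_ref"],
        max_mismatches_genome=cfg["catalog"]["max_mismatches_genome"],
    )
    catalog.to_csv(outdir / "catalog.tsv", sep="\t", lineterminator="\n")
    rejected.to_csv(outdir / "rejected_tags.tsv", sep="\t", index=False,
                    lineterminator="\n")
    sc.evidence_table(ev).to_csv(outdir / "evidence.tsv", sep="\t", index=False,
                                 lineterminator="\n")
    return [outdir / "catalog.tsv", outdir / "rejected_tags.tsv", outdir / "evidence.tsv"]


def _evidence_from_table(df: pd.DataFrame) -> list[sc.MappingEvidence]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            sc.MappingEvidence(
                tag=row.sequence,
                hits_mature_ref=bool(row.hits_mature_ref),
                mature_hit_id=row.mature_hit_id if isinstance(row.mature_hit_id, str) and row.mature_hit_id else None,
                mature_mismatches=int(row.mature_mismatches) if row.mature_mismatches >= 0 else None,
                mature_hit_ids=(),
                hits_precursor_ref=bool(row.hits_precursor_ref),
                precursor_hit_id=row.precursor_hit_id if isinstance(row.precursor_hit_id, str) and row.precursor_hit_id else None,
                precursor_maps_genome=bool(row.precursor_maps_genome),
                tag_maps_genome=bool(row.tag_maps_genome),
                genome_loci=_parse_loci(row.genome_loci if isinstance(row.genome_loci, str) else ""),
            )
        )
    return out


def stage_discover(cfg: dict, outdir: Path) -> list[Path]:
    ev_df = pd.read_csv(outdir / "evidence.tsv", sep="\t")
    genome = sc.GenomeIndex(_read_fasta_checked(outdir / "genome.fasta"))
    records = md.classify_catalog(
        _evidence_from_table(ev_df), genome, **cfg["discover"]
    )
    md.records_table(records).to_csv(outdir / "mirna_records.tsv", sep="\t",
                                     index=False, lineterminator="\n")
    md.summarize_groups(records).to_csv(outdir / "group_summary.tsv", sep="\t",
                                        lineterminator="\n")
    with open(outdir / "precursors.fasta", "w", newline="\n") as fh:
        for rec in records:
            if rec.precursor is not None:
                fh.write(f">{rec.id}\n{rec.precursor.precursor_seq}\n")
    with open(outdir / "precursors.struct", "w", newline="\n") as fh:
        for rec in records:
            if rec.precursor is not None:
                fh.write(f">{rec.id}\n{rec.precursor.precursor_seq}\n"
                         f"{rec.precursor.pairing}\n")
    return [outdir / "mirna_records.tsv", outdir / "group_summary.tsv",
            outdir / "precursors.fasta", outdir / "precursors.struct"]


def _long_de(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for label, df in results.items():
        d = df.reset_index()
        d.insert(0, "contrast", label)
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def de_contrast_results(
    normalized: pd.DataFrame, kind: str, cfg_de: dict
) -> dict[str, pd.DataFrame]:
    """All pairwise contrast results for one matrix ('dem' or 'deg')."""
    out: dict[str, pd.DataFrame] = {}
    for label, g, b, a in es.stage_pair_contrasts():
        libs_a = es.libraries_for(normalized.columns, genotype=g, stage=a)
        libs_b = es.libraries_for(normalized.columns, genotype=g, stage=b)
        out[label] = _one_contrast(normalized, libs_a, libs_b, kind, cfg_de)
    for label, s, b, a in es.genotype_pair_contrasts():
        libs_a = es.libraries_for(normalized.columns, genotype=a, stage=s)
        libs_b = es.libraries_for(normalized.columns, genotype=b, stage=s)
        out[label] = _one_contrast(normalized, libs_a, libs_b, kind, cfg_de)
    return out


def _one_contrast(normalized, libs_a, libs_b, kind, cfg_de):
    if kind == "dem":
        return es.dem_pairwise(normalized, libs_a, libs_b, alpha=cfg_de["dem_alpha"])
    return es.deg_call(
        normalized, libs_a, libs_b,
        fc_up=cfg_de["fc_up"], fc_down=cfg_de["fc_down"],
        alpha=cfg_de["deg_alpha"], pseudocount=cfg_de["pseudocount"],
    )


def stage_de(cfg: dict, outdir: Path) -> list[Path]:
    catalog = pd.read_csv(outdir / "catalog.tsv", sep="\t", index_col="sequence")
    mrna = pd.read_csv(outdir / "mrna_counts.tsv", sep="\t", index_col="transcript_id")
    info = pd.read_csv(outdir / "transcript_info.tsv", sep="\t",
                       index_col="transcript_id")
    cpm_s = es.normalize_cpm(catalog)
    cpm_m = es.normalize_cpm(mrna)

    # across-stage / across-genotype ANOVA DEM screens
    anova_rows = []
    for g in GENOTYPES:
        libs = es.libraries_for(cpm_s.columns, genotype=g)
        labels = {c: c.split("_")[1] for c in libs}
        res = es.dem_anova(cpm_s[libs], labels)
        res.insert(0, "factor", f"stages_within_{g}")
        anova_rows.append(res.reset_index(names="sequence"))
    for s in STAGES:
        libs = es.libraries_for(cpm_s.columns, stage=s)
        labels = {c: c.split("_")[0] for c in libs}
        res = es.dem_anova(cpm_s[libs], labels)
        res.insert(0, "factor", f"genotypes_within_{s}")
        anova_rows.append(res.reset_index(names="sequence"))
    pd.concat(anova_rows, ignore_index=True).to_csv(
        outdir / "dem_anova.tsv", sep="\t", index=False, lineterminator="\n"
    )

    dem = de_contrast_results(cpm_s, "dem", cfg["de"])
    deg = de_contrast_results(cpm_m, "deg", cfg["de"])
    _long_de(dem).rename(columns={"index": "sequence"}).to_csv(
        outdir / "dem_pairwise.tsv", sep="\t", index=False, lineterminator="\n"
    )
    _long_de(deg).rename(columns={"index": "transcript_id"}).to_csv(
        outdir / "deg_pairwise.tsv", sep="\t", index=False, lineterminator="\n"
    )
    es.fpkm_matrix(mrna, info["exon_length"]).to_csv(
        outdir / "fpkm.tsv", sep="\t", lineterminator="\n", float_format="%.6g"
    )
    return [outdir / "dem_anova.tsv", outdir / "dem_pairwise.tsv",
            outdir / "deg_pairwise.tsv", outdir / "fpkm.tsv"]


def stage_degradome(cfg: dict, outdir: Path) -> list[Path]:
    records = pd.read_csv(outdir / "mirna_records.tsv", sep="\t")
    mirnas = records[records["group"] != md.UNCLASSIFIED]
    transcripts = _read_fasta_checked(outdir / "transcripts.fasta")
    lengths = {t: len(s) for t, s in transcripts.items()}

    all_sites: list[td.TargetSite] = []
    for row in mirnas.itertuples(index=False):
        all_sites.extend(
            td.predict_targets(row.id, row.sequence, transcripts,
                               max_penalty=cfg["degradome"]["max_penalty"])
        )
    td.sites_table(all_sites).to_csv(outdir / "target_sites.tsv", sep="\t",
                                     index=False, lineterminator="\n")

    seq_of = dict(zip(mirnas["id"], mirnas["sequence"]))
    window = cfg["degradome"]["window"]
    rows = []
    for genotype in GENOTYPES:
        deg = pd.read_csv(outdir / f"degradome_{genotype}.tsv", sep="\t")
        profiles = td.build_profiles(deg, lengths, genotype)
        for site in all_sites:
            prof = td.profile_for(profiles, site.transcript_id, lengths, genotype)
            vc = td.validate_cleavage(site, prof, window=window)
            if vc is not None:
                rows.append(
                    {
                        "mirna_id": site.mirna_id,
                        "mirna_sequence": seq_of[site.mirna_id],
                        "transcript_id": site.transcript_id,
                        "genotype": genotype,
                        "site_start": site.start,
                        "site_end": site.end,
                        "expected_cleavage": site.cleavage_pos,
                        "peak_pos": vc.peak_pos,
                        "peak_count": vc.peak_count,
                        "transcript_max": vc.transcript_max,
                        "category": vc.category,
                    }
                )
    validated = pd.DataFrame(
        rows,
        columns=["mirna_id", "mirna_sequence", "transcript_id", "genotype",
                 "site_start", "site_end", "expected_cleavage", "peak_pos",
                 "peak_count", "transcript_max", "category"],
    )
    validated.to_csv(outdir / "validated_cleavages.tsv", sep="\t", index=False,
                     lineterminator="\n")
    return [outdir / "target_sites.tsv", outdir / "validated_cleavages.tsv"]


def _de_results_from_long(path: Path, key: str) -> dict[str, pd.DataFrame]:
    long = pd.read_csv(path, sep="\t")
    return {
        label: df.set_index(key).drop(columns=["contrast"])
        for label, df in long.groupby("contrast", sort=True)
    }


def validated_pairs_from_table(validated: pd.DataFrame):
    """Collapse per-genotype, per-site validations into unique pairs with
    their best (lowest) category; validation in ANY genotype counts."""
    pairs = []
    if validated.empty:
        return pairs
    grouped = validated.groupby(["mirna_id", "mirna_sequence", "transcript_id"],
                                sort=True)
    for (mid, mseq, tid), df in grouped:
        pairs.append((mid, mseq, tid, int(df["category"].min())))
    return pairs


def stage_integrate(cfg: dict, outdir: Path) -> list[Path]:
    dem = _de_results_from_long(outdir / "dem_pairwise.tsv", "sequence")
    deg = _de_results_from_long(outdir / "deg_pairwise.tsv", "transcript_id")
    validated = pd.read_csv(outdir / "validated_cleavages.tsv", sep="\t")
    info = pd.read_csv(outdir / "transcript_info.tsv", sep="\t")
    tf_map = {
        r.transcript_id: r.tf_family
        for r in info.itertuples(index=False)
        if isinstance(r.tf_family, str) and r.tf_family
    }
    unions = mi.build_union_sets(deg)
    modules = mi.find_antagonistic(
        dem, deg, unions, validated_pairs_from_table(validated), tf_families=tf_map
    )
    mi.modules_table(modules).to_csv(outdir / "modules.tsv", sep="\t", index=False,
                                     lineterminator="\n")
    edges, fams = mi.annotate_tf_modules(modules)
    edges.to_csv(outdir / "module_edges.tsv", sep="\t", index=False,
                 lineterminator="\n")
    fams.to_csv(outdir / "tf_family_counts.tsv", sep="\t", index=False,
                lineterminator="\n")
    with open(outdir / "deg_unions.json", "w", newline="\n") as fh:
        json.dump(
            {"developmental": sorted(unions[0]), "varietal": sorted(unions[1])},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    return [outdir / "modules.tsv", outdir / "module_edges.tsv",
            outdir / "tf_family_counts.tsv", outdir / "deg_unions.json"]


def stage_qpcr(cfg: dict, outdir: Path) -> list[Path]:
    ct_path = cfg["qpcr"].get("ct_table")
    calibrator = cfg["qpcr"].get("calibrator")
    if not ct_path or not calibrator:
        return []
    measurements = pd.read_csv(ct_path, sep="\t")
    rq = qq.relative_quantity(measurements, calibrator)
    rq.to_csv(outdir / "qpcr_rq.tsv", sep="\t", index=False, lineterminator="\n",
              float_format="%.6g")
    return [outdir / "qpcr_rq.tsv"]


STAGES_FN = {
    "simulate": stage_simulate,
    "catalog": stage_catalog,
    "discover": stage_discover,
    "de": stage_de,
    "degradome": stage_degradome,
    "integrate": stage_integrate,
    "qpcr": stage_qpcr,
}


def run(
    cfg: dict,
    outdir,
    stages: list[str] | None = None,
    resume: bool = False,
) -> dict:
    """Execute the pipeline and write a run manifest.

    A stage failure aborts with the stage named; earlier outputs are kept.
    With *resume*, stages whose recorded outputs all exist are skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGE_ORDER
    manifest: dict = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "stages": {},
        "outputs": {},
    }
    manifest_path = outdir / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text())

    for stage in stages:
        prev_outputs = [
            outdir / p
            for p in previous.get("stages", {}).get(stage, {}).get("outputs", [])
        ]
        if resume and prev_outputs and all(p.exists() for p in prev_outputs):
            logger.info("stage %s: resumed (outputs present)", stage)
            outputs = prev_outputs
        else:
            try:
                outputs = STAGES_FN[stage](cfg, outdir)
            except Exception as exc:
                manifest["stages"][stage] = {"complete": False, "error": str(exc)}
                _write_manifest(manifest_path, manifest)
                raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {
            "complete": True,
            "outputs": [str(p.relative_to(outdir)) for p in outputs],
        }
        for p in outputs:
            manifest["outputs"][p.name] = _digest(p)
    _write_manifest(manifest_path, manifest)
    return manifest


def _write_manifest(path: Path, manifest: dict) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
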