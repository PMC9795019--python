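"""Antagonistic miRNA-mRNA(-TF) regulatory module assembly.

A module is a degradome-validated miRNA-target pair whose two members are
significantly regulated in OPPOSITE directions in at least one shared
contrast (miRNA up and target down, or vice versa), the target belonging
to a DEG union set. Modules are labelled by evidence class:

- developmental: antagonism in a stage-pair-within-genotype contrast;
- varietal: antagonism in a genotype-pair-within-stage contrast;
- dual: antagonism in at least one contrast of each family.

Targets annotated as transcription factors extend the pair into a
miRNA->mRNA->TF-family module edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .expression_stats import contrast_family, union_all


@dataclass
class ModuleRecord:
    mirna_id: str
    mirna_sequence: str
    transcript_id: str
    tf_family: str | None
    contrasts: tuple[str, ...]  # contrasts in which antagonism holds
    mirna_direction: str  # direction in the first supporting contrast
    mrna_direction: str
    degradome_category: int
    evidence_class: str  # developmental | varietal | dual

    def __post_init__(self) -> None:
        if self.mirna_direction == self.mrna_direction:
            raise ValueError("module directions must be opposite")
        if self.degradome_category is None:
            raise ValueError("module requires degradome evidence")


def build_union_sets(
    deg_results: Mapping[str, pd.DataFrame],
) -> tuple[set, set]:
    """Union the significant DEGs of every contrast into a developmental
    set (stage-pair contrasts) and a varietal set (genotype-pair
    contrasts). Contrast labels follow the FD:DEvsBS / BS:LHvsFD scheme."""
    dev_sets, var_sets = [], []
    for label, df in deg_results.items():
        sig = set(df.index[df["significant"]])
        if contrast_family(label) == "developmental":
            dev_sets.append(sig)
        else:
            var_sets.append(sig)
    return union_all(dev_sets), union_all(var_sets)


def find_antagonistic(
    dem_results: Mapping[str, pd.DataFrame],
    deg_results: Mapping[str, pd.DataFrame],
    deg_unions: tuple[set, set],
    validated_pairs: Sequence[tuple[str, str, str, int]],
    mirna_sequences: Mapping[str, str] | None = None,
    tf_families: Mapping[str, str] | None = None,
) -> list[ModuleRecord]:
    """Emit one ModuleRecord per validated pair with opposite significant
    directions in some shared contrast.

    *validated_pairs* is [(mirna_id, mirna_sequence, transcript_id,
    degradome category), ...] from cleavage validation. DEM frames are
    indexed by tag sequence; DEG frames by transcript id.
    """
    dev_union, var_union = deg_unions
    tf_families = tf_families or {}
    shared = [c for c in dem_results if c in deg_results]
    modules: list[ModuleRecord] = []
    for mirna_id, mirna_seq, tid, category in validated_pairs:
        if tid not in dev_union and tid not in var_union:
            continue
        supporting: list[tuple[str, str, str]] = []
        for label in shared:
            dem = dem_results[label]
            deg = deg_results[label]
            if mirna_seq not in dem.index or tid not in deg.index:
                continue
            mdir = dem.loc[mirna_seq, "direction"]
            gdir = deg.loc[tid, "direction"]
            if mdir == "none" or gdir == "none" or mdir == gdir:
                continue
            supporting.append((label, mdir, gdir))
        if not supporting:
            continue
        families = {contrast_family(lbl) for lbl, _, _ in supporting}
        evidence_class = "dual" if len(families) == 2 else families.pop()
        label0, mdir0, gdir0 = supporting[0]
        modules.append(
            ModuleRecord(
                mirna_id=mirna_id,
                mirna_sequence=mirna_seq,
                transcript_id=tid,
                tf_family=tf_families.get(tid),
                contrasts=tuple(lbl for lbl, _, _ in supporting),
                mirna_direction=mdir0,
                mrna_direction=gdir0,
                degradome_category=category,
                evidence_class=evidence_class,
            )
        )
    return modules


def annotate_tf_modules(
    modules: Sequence[ModuleRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list for network export plus per-TF-family module counts.

    Every module yields a miRNA->mRNA edge; TF-annotated targets add an
    mRNA->TF-family edge.
    """
    edges = []
    family_counts: dict[str, int] = {}
    for m in modules:
        edges.append(
            {
                "source": m.mirna_id,
                "target": m.transcript_id,
                "edge_type": "cleaves",
                "evidence_class": m.evidence_class,
                "degradome_category": m.degradome_category,
                "contrasts": ";".join(m.contrasts),
            }
        )
        if m.tf_family:
            family_counts[m.tf_family] = family_counts.get(m.tf_family, 0) + 1
            edges.append(
                {
                    "source": m.transcript_id,
                    "target": m.tf_family,
                    "edge_type": "encodes_tf",
                    "evidence_class": m.evidence_class,
                    "degradome_category": m.degradome_category,
                    "contrasts": ";".join(m.contrasts),
                }
            )
    edge_df = pd.DataFrame(
        edges,
        columns=[
            "source", "target", "edge_type", "evidence_class",
            "degradome_category", "contrasts",
        ],
    )
    fam_df = pd.DataFrame(
        sorted(family_counts.items()), columns=["tf_family", "n_modules"]
    )
    return edge_df, fam_df


def modules_table(modules: Sequence[ModuleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": m.mirna_id,
                "mirna_sequence": m.mirna_sequence,
                "transcript_id": m.transcript_id,
                "tf_family": m.tf_family or "",
                "contrasts": ";".join(m.contrasts),
                "mirna_direction": m.mirna_direction,
                "mrna_direction": m.mrna_direction,
                "degradome_category": m.degradome_category,
                "evidence_class": m.evidence_class,
            }
            for m in modules
        ],
        columns=[
            "mirna_id", "mirna_sequence", "transcript_id", "tf_family",
            "contrasts", "mirna_direction", "mrna_direction",
            "degradome_category", "evidence_class",
        ],
    )
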