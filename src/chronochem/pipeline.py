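"""End-to-end orchestration: standardize → deglycosylate → group → descriptors
→ fragments → diversity statistics → biorelevance → chemical-space maps.

Every run writes a JSON manifest recording the configuration, seeds, and the
stage-by-stage attrition counts, which must satisfy

    read − invalid_cas − standardization_rejects − sugar_only
        = grouped + tail_dropped

per cohort.  Deglycosylation is applied to the NP cohort only by default
(synthetic compounds are essentially never glycosylated); optional stages
remove SC structures duplicating NP structures and subsample the SC cohort to
CAS-matched size.
"""

from __future__ import annotations

import dataclasses
import json
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from . import __version__
from .biorelevance import (
    br_score,
    np_likeness_score,
    reference_fingerprints,
    train_np_likeness,
)
from .chem_io import (
    CompoundRecord,
    Cohort,
    ReadResult,
    StandardizeConfig,
    dataclasses_replace_structure,
    parse_cas,
    read_compound_table,
    standardize,
)
from .chemspace import nonlinear_map, pca_fingerprints, pca_properties, tree_map
from .cohort import GroupedCohort, group_means, sort_and_group
from .deglyco import DeglycoParams, DeglycosylationResult, remove_sugars
from .descriptors import SCALAR_FIELDS, SHAPE_FIELDS, compute_descriptors
from .diversity_metrics import (
    FragmentType,
    build_ring_assembly_catalog,
    fragment_group_stats,
    glyco_group_stats,
    stats_frame,
)
from .fragments import decompose


@dataclass
class CohortCounts:
    read: int = 0
    invalid_cas: int = 0
    standardization_rejects: int = 0
    sugar_only: int = 0
    grouped: int = 0
    tail_dropped: int = 0

    @property
    def kept_after_attrition(self) -> int:
        return self.read - self.invalid_cas - self.standardization_rejects - self.sugar_only

    @property
    def attrition_identity_holds(self) -> bool:
        return self.kept_after_attrition == self.grouped + self.tail_dropped


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    seed: int = 0
    counts: dict[str, CohortCounts] = field(default_factory=dict)
    reject_reasons: dict[str, dict[str, int]] = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""
    failed_stage: str | None = None
    skipped: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        for label, c in payload["counts"].items():
            c["kept_after_attrition"] = self.counts[label].kept_after_attrition
            c["attrition_identity_holds"] = self.counts[label].attrition_identity_holds
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass(frozen=True)
class PipelineConfig:
    group_size: int = 500
    seed: int = 2016
    standardize: StandardizeConfig = StandardizeConfig()
    deglyco: DeglycoParams = DeglycoParams()
    deglyco_sc: bool = False
    exclude_sc_duplicates: bool = True
    cas_match_sc: bool = False
    recap_min_heavy: int = 4
    catalog_min_freq: int = 5
    shape_max_per_group: int = 25
    skip_chemspace: bool = False
    merge_duplicates: bool = False


def _prepare_cohort(
    source, label: Cohort, config: PipelineConfig, manifest: RunManifest
) -> tuple[list[CompoundRecord], dict[str, DeglycosylationResult]]:
    if isinstance(source, (str, Path)):
        read = read_compound_table(source, cohort=label)
    elif isinstance(source, ReadResult):
        read = source
    else:
        read = ReadResult(records=list(source), n_rows=len(source))
    counts = CohortCounts(read=read.n_rows, invalid_cas=read.n_dropped_bad_cas)
    reasons: Counter = Counter()
    kept: list[CompoundRecord] = []
    for rec in read.records:
        outcome = standardize(rec, config.standardize)
        if not outcome.kept:
            counts.standardization_rejects += 1
            reasons[outcome.reason.value] += 1
            continue
        kept.append(dataclasses_replace_structure(rec, outcome.structure))
    if config.merge_duplicates:
        seen: set[str] = set()
        unique = []
        for rec in kept:
            if rec.structure not in seen:
                seen.add(rec.structure)
                unique.append(rec)
        kept = unique
    deglyco_results: dict[str, DeglycosylationResult] = {}
    do_deglyco = label is Cohort.NP or config.deglyco_sc
    survivors: list[CompoundRecord] = []
    for rec in kept:
        if do_deglyco:
            res = remove_sugars(Chem.MolFromSmiles(rec.structure), config.deglyco)
            if res.sugar_only:
                counts.sugar_only += 1
                continue
            deglyco_results[rec.record_id] = res
            survivors.append(dataclasses_replace_structure(rec, res.aglycone))
        else:
            deglyco_results[rec.record_id] = DeglycosylationResult(rec.structure, 0, False)
            survivors.append(rec)
    manifest.counts[label.value] = counts
    manifest.reject_reasons[label.value] = dict(reasons)
    return survivors, deglyco_results


def _greedy_cas_match(
    np_records: Sequence[CompoundRecord], sc_records: Sequence[CompoundRecord]
) -> list[CompoundRecord]:
    """For each NP record pick the unused SC record with the nearest
    integerized (major, minor) CAS key; greedy, without replacement."""
    def intkey(r: CompoundRecord) -> int:
        k = parse_cas(r.cas)
        return k.major * 100 + k.minor

    pool = sorted(sc_records, key=intkey)
    keys = [intkey(r) for r in pool]
    used = [False] * len(pool)
    chosen: list[CompoundRecord] = []
    for rec in np_records:
        if all(used):
            break
        target = intkey(rec)
        idx = int(np.searchsorted(keys, target))
        # walk outward from the insertion point over unused candidates
        left, right = idx - 1, idx
        while used[left] if left >= 0 else False:
            left -= 1
        while used[right] if right < len(pool) else False:
            right += 1
        cand = []
        if left >= 0:
            cand.append((abs(keys[left] - target), left))
        if right < len(pool):
            cand.append((abs(keys[right] - target), right))
        _, j = min(cand)
        used[j] = True
        chosen.append(pool[j])
    return chosen


def run_pipeline(
    np_input,
    sc_input,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path = "chronochem_out",
    reference_structures: Sequence[str] | None = None,
) -> Path:
    """Execute the full analysis and write tables, plots and the manifest.

    ``np_input`` / ``sc_input``: a compound-table path, a ReadResult, or a
    sequence of CompoundRecord.  Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            **dataclasses.asdict(config, dict_factory=_json_safe_dict),
            "reference_set_size": len(reference_structures or []),
        },
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    try:
        np_records, np_deglyco = _prepare_cohort(np_input, Cohort.NP, config, manifest)
        sc_records, sc_deglyco = _prepare_cohort(sc_input, Cohort.SC, config, manifest)

        if config.exclude_sc_duplicates:
            np_structures = {r.structure for r in np_records}
            before = len(sc_records)
            sc_records = [r for r in sc_records if r.structure not in np_structures]
            manifest.counts["SC"].standardization_rejects += before - len(sc_records)
        if config.cas_match_sc and len(sc_records) > len(np_records):
            matched = _greedy_cas_match(np_records, sc_records)
            dropped = len(sc_records) - len(matched)
            sc_records = matched
            manifest.counts["SC"].standardization_rejects += dropped

        grouped: dict[str, GroupedCohort] = {}
        mols: dict[str, Chem.Mol] = {}
        records_by_id: dict[str, CompoundRecord] = {}
        for label, records in (("NP", np_records), ("SC", sc_records)):
            g = sort_and_group(records, config.group_size)
            grouped[label] = g
            manifest.counts[label].grouped = g.n_grouped
            manifest.counts[label].tail_dropped = len(g.dropped)
            for r in records:
                records_by_id[r.record_id] = r
                mols[r.record_id] = Chem.MolFromSmiles(r.structure)

        # --- group assignments ---------------------------------------------
        pd.DataFrame(
            {"record_id": rid, "cohort": label, "group_index": gi}
            for label, g in grouped.items()
            for rid, gi in g.group_of().items()
        ).to_csv(out / "group_assignments.csv", index=False)

        # --- descriptors ----------------------------------------------------
        rng = np.random.default_rng(config.seed)
        desc_rows = []
        for label, g in grouped.items():
            for grp in g.groups:
                shape_ids = set(
                    rng.choice(
                        grp.members,
                        size=min(config.shape_max_per_group, len(grp.members)),
                        replace=False,
                    )
                )
                for rid in grp.members:
                    vec = compute_descriptors(
                        mols[rid],
                        record_id=rid,
                        with_shape=rid in shape_ids,
                        seed=config.seed,
                    )
                    row = vec.as_dict()
                    row["cohort"] = label
                    row["group_index"] = grp.index
                    desc_rows.append(row)
        desc_df = pd.DataFrame(desc_rows)
        desc_df.to_csv(out / "descriptors.csv", index=False)
        mean_rows = []
        for label, g in grouped.items():
            sub = desc_df[desc_df["cohort"] == label]
            for name in SCALAR_FIELDS + SHAPE_FIELDS:
                values = dict(zip(sub["record_id"], sub[name]))
                gm = group_means(g, values)
                gm.insert(0, "cohort", label)
                gm.insert(1, "descriptor", name)
                mean_rows.append(gm)
        means_df = pd.concat(mean_rows, ignore_index=True)
        means_df.to_csv(out / "group_descriptor_means.csv", index=False)

        # --- fragments & diversity -----------------------------------------
        fragsets = {
            rid: decompose(mol, rid, min_heavy=config.recap_min_heavy)
            for rid, mol in mols.items()
        }
        frag_stats = []
        for label, g in grouped.items():
            for ftype in FragmentType:
                frag_stats.append(
                    stats_frame(fragment_group_stats(g, fragsets, ftype), label)
                )
        pd.concat(frag_stats, ignore_index=True).to_csv(
            out / "fragment_group_stats.csv", index=False
        )
        glyco = glyco_group_stats(grouped["NP"], np_deglyco)
        pd.DataFrame(
            {
                "group_index": s.group_index,
                "glycosylation_ratio": s.glycosylation_ratio,
                "mean_sugar_rings_per_glycoside": s.mean_sugar_rings_per_glycoside,
            }
            for s in glyco
        ).to_csv(out / "glyco_group_stats.csv", index=False)

        catalog = build_ring_assembly_catalog(
            [
                (fragsets[rid].ring_assemblies, parse_cas(records_by_id[rid].cas))
                for rid in grouped["NP"].member_ids()
            ],
            [
                (fragsets[rid].ring_assemblies, parse_cas(records_by_id[rid].cas))
                for rid in grouped["SC"].member_ids()
            ],
            min_freq=config.catalog_min_freq,
        )
        catalog.to_frame().to_csv(out / "ring_assembly_catalog.csv", index=False)

        # --- biorelevance ----------------------------------------------------
        np_ids = grouped["NP"].member_ids()
        sc_ids = grouped["SC"].member_ids()
        table = train_np_likeness(
            [records_by_id[r].structure for r in np_ids],
            [records_by_id[r].structure for r in sc_ids],
        )
        table.to_json(out / "np_likeness_table.json")
        ref_fps = (
            reference_fingerprints(reference_structures) if reference_structures else None
        )
        score_rows = []
        for label in ("NP", "SC"):
            for rid in grouped[label].member_ids():
                score_rows.append(
                    {
                        "record_id": rid,
                        "cohort": label,
                        "np_likeness": np_likeness_score(mols[rid], table),
                        "br_score": br_score(mols[rid], ref_fps) if ref_fps else None,
                    }
                )
        scores_df = pd.DataFrame(score_rows)
        scores_df.to_csv(out / "biorelevance_scores.csv", index=False)

        # --- chemical space --------------------------------------------------
        if config.skip_chemspace:
            manifest.skipped.append("chemspace")
        else:
            _chemspace_outputs(out, desc_df, mols, grouped, catalog, config)

        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    except Exception:
        manifest.failed_stage = "see traceback"
        manifest.to_json(out / "manifest.json")
        raise
    manifest.to_json(out / "manifest.json")
    _plots(out)
    return out


def _json_safe_dict(items):
    out = {}
    for k, v in items:
        if isinstance(v, frozenset):
            v = sorted(v)
        out[k] = v
    return out


def _chemspace_outputs(out, desc_df, mols, grouped, catalog, config):
    prop_cols = [c for c in SCALAR_FIELDS]
    matrix = desc_df[prop_cols]
    emb = pca_properties(matrix, color_key=list(desc_df["cohort"]))
    pd.DataFrame(
        {
            "record_id": desc_df["record_id"],
            "x": emb.coordinates[:, 0],
            "y": emb.coordinates[:, 1],
            "color_key": desc_df["cohort"],
            "group_index": desc_df["group_index"],
        }
    ).to_csv(out / "pca_properties.csv", index=False)
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(emb.explained_variance))],
         "explained_variance": emb.explained_variance}
    ).to_csv(out / "pca_properties_variance.csv", index=False)

    fps = np.array(
        [np.array(MACCSkeys.GenMACCSKeys(mols[rid])) for rid in desc_df["record_id"]]
    )
    emb_fp = pca_fingerprints(fps, color_key=list(desc_df["cohort"]))
    pd.DataFrame(
        {
            "record_id": desc_df["record_id"],
            "x": emb_fp.coordinates[:, 0],
            "y": emb_fp.coordinates[:, 1],
            "color_key": desc_df["cohort"],
        }
    ).to_csv(out / "pca_fingerprints.csv", index=False)

    if len(catalog) >= 2:
        assembly_mols = [Chem.MolFromSmiles(e.assembly) for e in catalog.entries]
        cat_fps = np.array(
            [np.array(MACCSkeys.GenMACCSKeys(m)) for m in assembly_mols]
        )
        categories = [e.category.value for e in catalog.entries]
        tm = tree_map(
            [e.assembly for e in catalog.entries],
            cat_fps,
            color_key=categories,
            seed=config.seed,
        )
        pd.DataFrame(
            {"i": i, "j": j, "distance": w} for i, j, w in tm.edges
        ).to_csv(out / "treemap_edges.csv", index=False)
        pd.DataFrame(
            {
                "assembly": tm.nodes,
                "x": tm.positions[:, 0],
                "y": tm.positions[:, 1],
                "category": categories,
                "size": [e.freq_NP + e.freq_SC for e in catalog.entries],
            }
        ).to_csv(out / "treemap_nodes.csv", index=False)

        from .chemspace import jaccard_distance_matrix

        nlm = nonlinear_map(jaccard_distance_matrix(cat_fps), color_key=categories)
        pd.DataFrame(
            {
                "assembly": [e.assembly for e in catalog.entries],
                "x": nlm.coordinates[:, 0],
                "y": nlm.coordinates[:, 1],
                "category": categories,
                "size": [e.freq_NP + e.freq_SC for e in catalog.entries],
            }
        ).to_csv(out / "nonlinear_map.csv", index=False)


def _plots(out: Path) -> None:
    """Static summary figures from the written tables (best effort)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = pd.read_csv(out / "group_descriptor_means.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sub in means[means["descriptor"] == "mol_weight"].groupby("cohort"):
        ax.plot(sub["group_index"], sub["mean"], marker="o", label=label)
    ax.set_xlabel("chronological group")
    ax.set_ylabel("mean molecular weight (Da)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "mw_trend.png", dpi=120)
    plt.close(fig)

    stats = pd.read_csv(out / "fragment_group_stats.csv")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for metric, ax in zip(("abundance", "uniqueness", "novelty"), axes):
        for (cohort, ftype), sub in stats.groupby(["cohort", "fragment_type"]):
            if ftype != "scaffold":
                continue
            ax.plot(sub["group_index"], sub[metric], marker=".", label=cohort)
        ax.set_title(f"scaffold {metric}")
        ax.set_xlabel("group")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out / "scaffold_diversity.png", dpi=120)
    plt.close(fig)

    pca_path = out / "pca_properties.csv"
    if pca_path.exists():
        pca = pd.read_csv(pca_path)
        fig, ax = plt.subplots(figsize=(5, 5))
        for label, sub in pca.groupby("color_key"):
            ax.scatter(sub["x"], sub["y"], s=4, alpha=0.4, label=label)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "pca_properties.png", dpi=120)
        plt.close(fig)
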