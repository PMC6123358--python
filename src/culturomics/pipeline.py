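"""End-to-end orchestration: load or simulate, preprocess, account, test, report.

``run_pipeline`` executes the full analysis in stages — low-count
filtering, Venn partitioning and cultivability accounting on the
non-rarefied table, the rare-biosphere cohort survey, the phylogenetic
cohesion permutation test (when distances are available), and the
rarefied-table branch (ordination, two-way PERMANOVA, richness tests,
percentile abundance-cultivability correlations).  Any stage failure
aborts with the stage name; output files are only written after every
stage succeeded, so no partial outputs remain.

Raw fractions live in ``results.json``; percent formatting (truncation
for whole percents) is applied only by :func:`render_summary`.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import accounting, core, phylo, simulate, stats
from .formatting import percent_truncated

_ANALYSIS_SUBSTREAMS = ("rarefy", "permanova", "phylo")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Inputs and tuning parameters of one analysis run.

    Exactly one of (``table_path`` + ``metadata_path``) or ``simulation``
    must be supplied.  Distances for the cohesion test come from, in order
    of precedence: an explicit matrix, an aligned FASTA, a Newick tree, or
    (for simulated input) the simulated tree.
    """

    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    alignment_path: str | None = None
    distances_path: str | None = None
    simulation: simulate.SimulationParams | None = None
    rarefaction_depth: int | None = None   # default: minimum sample total
    low_count_max_total: int = 2
    phylo_permutations: int = 100
    min_family_otus: int = 10
    permanova_permutations: int = 1000
    n_bins: int = 100
    r_threshold: float = 0.3
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_paths = self.table_path is not None and self.metadata_path is not None
        if has_paths == (self.simulation is not None):
            raise ValueError(
                "supply exactly one of (table_path and metadata_path) or simulation"
            )

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            out["simulation"] = dataclasses.asdict(self.simulation)
        return out


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_ANALYSIS_SUBSTREAMS))
    return {
        name: np.random.default_rng(child)
        for name, child in zip(_ANALYSIS_SUBSTREAMS, children)
    }


def _stage_load(config: PipelineConfig):
    taxonomy = None
    distances = None
    if config.simulation is not None:
        bundle = simulate.simulate_experiment(config.simulation)
        table, metadata = bundle.table, bundle.metadata
        distances = phylo.patristic_distances(bundle.truth.tree)
    else:
        table = core.read_otu_table(config.table_path)
        metadata = core.read_metadata(config.metadata_path)
    unknown = set(table.sample_ids) ^ set(metadata.index)
    if unknown:
        raise ValueError(f"table and metadata samples differ: {sorted(unknown)[:5]}")
    if config.taxonomy_path:
        taxonomy = core.read_taxonomy(config.taxonomy_path)
    if config.distances_path:
        distances = phylo.read_distance_matrix(config.distances_path)
    elif config.alignment_path:
        distances = phylo.pdistance_from_alignment(config.alignment_path)
    elif config.tree_path:
        distances = phylo.patristic_distances(config.tree_path)
    return table, metadata, taxonomy, distances


def _stage_accounting(table, metadata, config) -> dict:
    partition = accounting.partition_otus(table, metadata)
    gains = {
        medium: accounting.medium_gain(partition, medium)
        for medium in ("defined", "undefined")
    }
    section = {
        "partition": partition.cardinalities(),
        "cultivability": {
            "cultivable_fraction": accounting.cultivable_fraction(partition),
            "medium_gain": gains,
            "medium_gain_max": max(gains.values()),
        },
        "shared_per_dilution": [
            {"dilution_exponent": d, "medium": m, "proportion": v}
            for (d, m), v in accounting.shared_per_dilution(table, metadata).items()
        ],
    }
    rare = accounting.rare_biosphere(partition)
    rare_section: dict[str, Any] = {"n_otus": len(rare)}
    cohort_ids = core.cohort_sample_ids(metadata)
    survey = None
    if cohort_ids and rare:
        cohort_table = core.OtuTable(
            table.data.loc[cohort_ids], validate=False
        )
        survey = accounting.cohort_survey(rare, cohort_table)
        rare_section["n_cohort_samples"] = len(cohort_ids)
        rare_section["fraction_never_detected_in_cohort"] = float(
            (survey["n_detected"] == 0).mean()
        )
        rare_section["mean_detection_frequency"] = float(
            survey["detection_frequency"].mean()
        )
    section["rare_biosphere"] = rare_section
    return section, partition, survey


def _stage_phylo(partition, distances, taxonomy, config, rng) -> dict | None:
    if distances is None:
        return None
    ids = set(distances.ids)
    focal = sorted(partition.plates_all & ids)
    pool = sorted(partition.rumen_all & ids)
    if len(focal) < 2 or len(pool) < 2:
        return None
    subset_size = min(len(focal), len(pool))
    seed = int(rng.integers(2**31))
    result = phylo.phylo_permutation_test(
        focal,
        pool,
        distances,
        B=config.phylo_permutations,
        subset_size=subset_size,
        seed=seed,
        group_label="all_cultured",
    )
    section = {"global": result.to_dict()}
    if taxonomy is not None:
        fam_seed = int(rng.integers(2**31))
        fam_results, skipped = phylo.family_cohesion_tests(
            focal,
            pool,
            taxonomy,
            distances,
            B=config.phylo_permutations,
            min_otus=config.min_family_otus,
            seed=fam_seed,
        )
        section["families"] = [r.to_dict(include_null=False) for r in fam_results]
        section["families_skipped"] = skipped
    return section


def _stage_ordination(table, metadata, config, rng) -> tuple[dict, core.OtuTable, list]:
    keep = [
        s
        for s in table.sample_ids
        if metadata.loc[s, "source"] in ("rumen", "plate")
    ]
    sub = core.OtuTable(table.data.loc[keep], validate=False)
    totals = sub.sample_totals()
    depth = config.rarefaction_depth or int(totals[totals > 0].min())
    excluded = core.samples_below_depth(sub, depth)
    included = [s for s in keep if s not in excluded]
    rarefied = core.rarefy(
        core.OtuTable(sub.data.loc[included], validate=False), depth, rng
    )
    D = stats.euclidean_distances(rarefied)
    ordination = stats.pcoa(D)
    medium = metadata.loc[included, "medium"]
    dilution = metadata.loc[included, "dilution_exponent"].astype(str)
    perm_seed = int(rng.integers(2**31))
    results = {}
    for order_name, fa, fb, na, nb in (
        ("medium_first", medium, dilution, "medium", "dilution"),
        ("dilution_first", dilution, medium, "dilution", "medium"),
    ):
        res = stats.permanova_two_way(
            D,
            fa,
            fb,
            B=config.permanova_permutations,
            seed=perm_seed,
            names=(na, nb),
        )
        results[order_name] = {
            "factors": [dataclasses.asdict(f) for f in res.factors],
            "residual_ss": res.residual_ss,
            "residual_df": res.residual_df,
            "total_ss": res.total_ss,
            "B": res.B,
            "seed": res.seed,
        }
    section = {
        "rarefaction_depth": depth,
        "excluded_samples": excluded,
        "pcoa": {
            "eigenvalues": ordination.eigenvalues.tolist(),
            "proportion_explained": ordination.proportion_explained.tolist(),
            "coordinates": {
                s: ordination.coordinates.loc[s].tolist()
                for s in ordination.coordinates.index
            },
        },
        "permanova": results,
    }
    return section, rarefied, excluded


def _stage_richness(rarefied, metadata, config) -> dict:
    richness = core.observed_richness(rarefied)
    meta = metadata.loc[richness.index]
    plate_dilutions = sorted(
        meta.loc[meta["source"] == "plate", "dilution_exponent"].unique()
    )
    comparisons = []
    for medium in ("defined", "undefined"):
        rumen_vals, plate_vals = [], []
        for d in plate_dilutions:
            r_ids = meta.index[
                (meta["source"] == "rumen") & (meta["dilution_exponent"] == d)
            ]
            p_ids = meta.index[
                (meta["source"] == "plate")
                & (meta["medium"] == medium)
                & (meta["dilution_exponent"] == d)
            ]
            if len(r_ids) == 0 or len(p_ids) == 0:
                continue
            rumen_vals.append(float(richness.loc[r_ids].mean()))
            plate_vals.append(float(richness.loc[p_ids].mean()))
        if len(rumen_vals) >= 2 and any(
            r != p for r, p in zip(rumen_vals, plate_vals)
        ):
            p_val = stats.wilcoxon_signed_rank_exact(rumen_vals, plate_vals)
            comparisons.append(
                {
                    "comparison": f"rumen_vs_{medium}",
                    "n_pairs": len(rumen_vals),
                    "p_raw": p_val,
                }
            )
    if comparisons:
        adjusted = stats.holm_bonferroni([c["p_raw"] for c in comparisons])
        for c, p in zip(comparisons, adjusted):
            c["p_adjusted"] = float(p)
    groups = {
        "rumen": richness.loc[meta["source"] == "rumen"].tolist(),
        "defined": richness.loc[
            (meta["source"] == "plate") & (meta["medium"] == "defined")
        ].tolist(),
        "undefined": richness.loc[
            (meta["source"] == "plate") & (meta["medium"] == "undefined")
        ].tolist(),
    }
    h, kw_p = stats.kruskal_wallis([g for g in groups.values() if g])
    medium_p = (
        stats.wilcoxon_rank_sum_exact(groups["defined"], groups["undefined"])
        if groups["defined"] and groups["undefined"]
        else None
    )
    return {
        "observed_richness": {s: int(v) for s, v in richness.items()},
        "paired_rumen_vs_medium": comparisons,
        "kruskal_wallis": {"H": h, "p": kw_p},
        "defined_vs_undefined_rank_sum_p": medium_p,
    }


def _stage_correlation(table, metadata, config) -> dict:
    plate_meta = metadata[metadata["source"] == "plate"]
    cells: list[dict] = []
    for d in sorted(plate_meta["dilution_exponent"].unique()):
        rumen_ids = metadata.index[
            (metadata["source"] == "rumen") & (metadata["dilution_exponent"] == d)
        ]
        if len(rumen_ids) == 0:
            continue
        sample = table.data.loc[rumen_ids[0]]
        n_detected = int((sample > 0).sum())
        if n_detected < 3:
            continue
        defined = accounting.detected_otus(
            table, core.plate_sample_ids(metadata, "defined", int(d))
        )
        undefined = accounting.detected_otus(
            table, core.plate_sample_ids(metadata, "undefined", int(d))
        )
        subsets = {
            "total": defined | undefined,
            "defined_unique": defined - undefined,
            "undefined_unique": undefined - defined,
            "both_media": defined & undefined,
        }
        n_bins = min(config.n_bins, n_detected)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_subset = stats.percentile_cultivability_correlation(
                sample, subsets, n_bins=n_bins
            )
        for label, cell in per_subset.items():
            cell.update({"dilution_exponent": int(d), "subset": label})
            cells.append(cell)
    stats.apply_significance(cells, config.r_threshold, config.alpha)
    return {"cells": cells, "r_threshold": config.r_threshold, "alpha": config.alpha}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the results bundle (a JSON-ready dict).

    When ``config.out_dir`` is set, writes ``results.json``,
    ``pcoa_coordinates.tsv`` and ``rare_biosphere_survey.tsv`` there after
    all stages succeed.
    """
    rngs = _substreams(config.seed)

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    table, metadata, taxonomy, distances = stage("load", _stage_load, config)
    filtered = stage(
        "filter", core.filter_low_count_otus, table, config.low_count_max_total
    )
    acc_section, partition, survey = stage(
        "accounting", _stage_accounting, filtered, metadata, config
    )
    phylo_section = stage(
        "phylo", _stage_phylo, partition, distances, taxonomy, config, rngs["phylo"]
    )
    ord_section, rarefied, _ = stage(
        "ordination", _stage_ordination, filtered, metadata, config, rngs["rarefy"]
    )
    richness_section = stage("richness", _stage_richness, rarefied, metadata, config)
    corr_section = stage("correlation", _stage_correlation, filtered, metadata, config)

    results = {
        "config": config.echo(),
        "seed": config.seed,
        "samples": {
            "n_samples": len(table.sample_ids),
            "n_otus_raw": len(table.otu_ids),
            "n_otus_filtered": len(filtered.otu_ids),
            "by_source": metadata["source"].value_counts().to_dict(),
        },
        **acc_section,
        "phylo": phylo_section,
        "ordination": ord_section,
        "richness_tests": richness_section,
        "percentile_correlation": corr_section,
    }
    validate_results(results)
    if config.out_dir:
        stage("write", _write_outputs, results, survey, config)
    return results


def _write_outputs(results: dict, survey, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results.json").write_text(
        json.dumps(round_floats(results), indent=1, allow_nan=False) + "\n",
        encoding="utf-8",
    )
    coords = results["ordination"]["pcoa"]["coordinates"]
    with open(out / "pcoa_coordinates.tsv", "w", encoding="utf-8", newline="\n") as fh:
        n_axes = max((len(v) for v in coords.values()), default=0)
        fh.write("sample_id\t" + "\t".join(f"PC{i+1}" for i in range(n_axes)) + "\n")
        for sid, row in coords.items():
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    if survey is not None:
        survey_out = survey.copy()
        survey_out.index.name = "otu_id"
        survey_out.to_csv(out / "rare_biosphere_survey.tsv", sep="\t")


def round_floats(obj: Any, sig: int = 12) -> Any:
    """Recursively round floats to ``sig`` significant digits for JSON.

    Non-finite floats become None so the output is strict JSON.
    """
    if isinstance(obj, float):
        if not np.isfinite(obj):
            return None
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round_floats(float(obj), sig)
    return obj


def validate_results(results: dict) -> None:
    """Check the results bundle against the shipped section schema."""
    schema = json.loads(
        resources.files("culturomics").joinpath("results_schema.json").read_text()
    )
    for section, kind in schema["sections"].items():
        if section not in results:
            raise ValueError(f"results missing section {section!r}")
        value = results[section]
        if kind == "object" and not isinstance(value, dict):
            raise ValueError(f"section {section!r} must be an object")
        if kind == "object_or_null" and not (value is None or isinstance(value, dict)):
            raise ValueError(f"section {section!r} must be an object or null")
    for key in schema["required_keys"]:
        section, sub = key.split(".", 1)
        if sub not in results.get(section, {}):
            raise ValueError(f"results missing {key!r}")


def render_summary(results: dict) -> str:
    """Human-readable headline summary (whole percents by truncation)."""
    lines = []
    part = results["partition"]
    cult = results["cultivability"]
    lines.append(
        f"cultivable: {percent_truncated(cult['cultivable_fraction'])}% "
        f"({part['shared']} of {part['rumen_all']} rumen OTUs on plates)"
    )
    gains = cult["medium_gain"]
    best = max(gains, key=gains.get)
    lines.append(
        "medium gain: up to "
        f"{percent_truncated(cult['medium_gain_max'])}% (adding {best} medium)"
    )
    rare = results["rare_biosphere"]
    lines.append(f"rare biosphere: {rare['n_otus']} OTUs")
    if "fraction_never_detected_in_cohort" in rare:
        lines.append(
            "  never detected in cohort: "
            f"{percent_truncated(rare['fraction_never_detected_in_cohort'])}% "
            f"of them (over {rare['n_cohort_samples']} microbiomes)"
        )
    if results.get("phylo"):
        g = results["phylo"]["global"]
        lines.append(
            f"phylogenetic cohesion: cultured MPD at percentile "
            f"{g['percentile_rank']:.1f} of the null (p_lesser={g['p_lesser']:.4g})"
        )
    ordn = results["ordination"]
    prop = ordn["pcoa"]["proportion_explained"]
    if len(prop) >= 2:
        lines.append(
            f"PCoA: axis1 {100 * prop[0]:.1f}%, axis2 {100 * prop[1]:.1f}% of variance"
        )
    for factor in ordn["permanova"]["medium_first"]["factors"]:
        lines.append(
            f"PERMANOVA {factor['name']}: R2={factor['variance_explained']:.3f} "
            f"p={factor['p_value']:.4g}"
        )
    return "\n".join(lines)
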