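"""Ground-truthed simulator for dilution-to-extinction plating experiments.

The generator emulates the statistical structure of a culturomics study of
a dense gut community:

* a heavy-tailed (log-normal) community with an abundant core and an
  extensive rare biosphere;
* a decimal dilution series of the sample, each dilution sequenced
  alongside the undiluted original;
* duplicate plating of every dilution on two agar media, where an
  undefined medium (supplemented with habitat fluid) raises every taxon's
  odds of growing;
* tree-correlated cultivability: the propensity to grow on a plate is a
  latent "liability" evolving as Brownian motion along a phylogeny plus an
  independent per-taxon component, mapped through a logistic link — so the
  cultured set is phylogenetically cohesive without being confined to one
  clade;
* a cohort of additional host animals sharing the same taxon universe and
  ecosystem-level abundance structure, against which plate-detected taxa
  can be surveyed.

Cultivability is independent of abundance by construction: any observed
abundance-cultivability correlation downstream must emerge from Poisson
founder sampling of the plated aliquot, which is exactly what makes the
simulator a meaningful test bed for the analysis.

All randomness flows from one master seed through named substreams (tree,
truth, rumen, plates, cohort) so each component is independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import OtuTable, validate_metadata

_SUBSTREAMS = ("tree", "truth", "rumen", "plates", "cohort")


@dataclass
class SimulationParams:
    """Knobs of the simulated cultivation experiment.

    Defaults describe a desk-scale experiment mirroring a single-cow study
    design: a 3,000-taxon community, an aliquot of ~1e7 cells plated across
    decimal dilutions 10^-1..10^-6 in duplicate on two media, sequencing to
    8,078 reads per sample, and a 38-animal cohort.
    """

    n_taxa: int = 3000
    abundance_sigma: float = 2.5          # log-normal shape of relative abundances
    inoculum_cells: float = 1e7           # expected cells in the undiluted plated aliquot
    dilution_exponents: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    media: tuple[str, ...] = ("defined", "undefined")
    replicates: int = 2
    read_depth: int = 8078
    cultivability_base: float = 0.05      # baseline growth probability on defined medium
    undefined_medium_log_odds_boost: float = 1.2
    phylo_signal_variance: float = 1.0    # Brownian variance of the liability over unit tree height
    independent_noise_variance: float = 0.25
    growth_dispersion: float = 0.8        # log-normal sigma of per-taxon colony growth factor
    n_cohort_samples: int = 38
    cohort_log_abundance_sigma: float = 1.0  # between-animal spread of log abundance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0 < self.cultivability_base < 1:
            raise ValueError("cultivability_base must lie in (0, 1)")
        for name in ("abundance_sigma", "inoculum_cells"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "phylo_signal_variance",
            "independent_noise_variance",
            "growth_dispersion",
            "cohort_log_abundance_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.read_depth < 1 or self.replicates < 1:
            raise ValueError("read_depth and replicates must be >= 1")
        if self.n_cohort_samples < 0:
            raise ValueError("n_cohort_samples must be >= 0")

    def substreams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))
        return {
            name: np.random.default_rng(child)
            for name, child in zip(_SUBSTREAMS, children)
        }


@dataclass
class SyntheticTruth:
    """Ground truth underlying one simulated experiment.

    ``cultivability[medium][i]`` is the probability that one plated cell of
    taxon ``taxon_ids[i]`` founds a colony on that medium.
    """

    taxon_ids: list[str]
    tree: dendropy.Tree
    newick: str
    abundance: np.ndarray            # relative abundances, sum to 1
    liability: np.ndarray            # Brownian trait + independent noise
    cultivability: dict[str, np.ndarray]
    growth_factor: np.ndarray        # per-taxon colony growth multiplier


@dataclass
class ExperimentBundle:
    truth: SyntheticTruth
    table: OtuTable
    metadata: pd.DataFrame
    flagged: list[str] = field(default_factory=list)  # samples emitted all-zero


# ---------------------------------------------------------------------------
# tree


def _yule_times(n_taxa: int, rng: np.random.Generator):
    """Speciation times of a pure-birth (Yule, rate 1) tree with n_taxa tips."""
    # node records: (parent_index, birth_time); root has parent -1
    parents = [-1]
    births = [0.0]
    children: list[list[int]] = [[]]
    active = [0]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        u = active.pop(int(rng.integers(k)))
        for _ in range(2):
            parents.append(u)
            births.append(t)
            children[u].append(len(parents) - 1)
            children.append([])
            active.append(len(parents) - 1)
    t += rng.exponential(1.0 / n_taxa)  # extend tips to the present
    return parents, births, children, active, t


def simulate_tree(n_taxa: int, seed: int | np.random.Generator) -> dendropy.Tree:
    """Simulate a rooted ultrametric Yule tree, scaled to unit height.

    Tip labels are ``otu00001`` .. in order of lineage creation, so the
    same seed always yields the same Newick string.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parents, births, children, tips, present = _yule_times(n_taxa, rng)
    tip_label = {}
    for i, node in enumerate(sorted(tips), start=1):
        tip_label[node] = f"otu{i:05d}"
    # The root's own edge (origin to first split) is dropped when rendering,
    # so scale by the height below the first split to get unit tree height.
    height = present - births[children[0][0]]

    def node_newick(node: int) -> str:
        end = present if not children[node] else births[children[node][0]]
        length = (end - births[node]) / height
        if not children[node]:
            return f"{tip_label[node]}:{length:.10f}"
        inner = ",".join(node_newick(c) for c in children[node])
        return f"({inner}):{length:.10f}"

    # iterative-safe: Yule trees are shallow (depth ~ 2 ln n) but allow margin
    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n_taxa + 1000))
    try:
        newick = node_newick(0).rsplit(":", 1)[0] + ";"
    finally:
        sys.setrecursionlimit(old_limit)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree


def _brownian_tip_values(
    tree: dendropy.Tree, variance: float, rng: np.random.Generator
) -> dict[str, float]:
    """Brownian motion along the tree; returns tip-label -> trait value."""
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            length = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(variance * length)) if variance > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


# ---------------------------------------------------------------------------
# truth


def simulate_truth(params: SimulationParams) -> SyntheticTruth:
    """Draw community abundances and the cultivability model.

    * abundance: normalized log-normal(0, ``abundance_sigma``) draws;
    * liability: Brownian motion along the tree (tip variance
      ``phylo_signal_variance`` at unit height) plus independent
      Normal(0, ``independent_noise_variance``) noise;
    * cultivability(taxon, medium) = logistic(logit(base) + liability
      + boost * 1[medium is undefined]);
    * growth factor: log-normal(0, ``growth_dispersion``).
    """
    streams = params.substreams()
    tree = simulate_tree(params.n_taxa, streams["tree"])
    taxon_ids = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())

    rng = streams["truth"]
    raw = rng.lognormal(0.0, params.abundance_sigma, params.n_taxa)
    abundance = raw / raw.sum()

    brownian = _brownian_tip_values(tree, params.phylo_signal_variance, rng)
    noise = rng.normal(
        0.0, np.sqrt(params.independent_noise_variance), params.n_taxa
    )
    liability = np.array([brownian[t] for t in taxon_ids]) + noise

    base_logit = logit(params.cultivability_base)
    cultivability = {}
    for medium in params.media:
        boost = (
            params.undefined_medium_log_odds_boost if medium == "undefined" else 0.0
        )
        cultivability[medium] = expit(base_logit + liability + boost)

    growth_factor = rng.lognormal(0.0, params.growth_dispersion, params.n_taxa)
    return SyntheticTruth(
        taxon_ids=taxon_ids,
        tree=tree,
        newick=tree.as_string(schema="newick").strip(),
        abundance=abundance,
        liability=liability,
        cultivability=cultivability,
        growth_factor=growth_factor,
    )


# ---------------------------------------------------------------------------
# sampling layers


def poisson_cells(
    abundance: np.ndarray, expected_total: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-taxon cell counts in an aliquot with ``expected_total`` cells."""
    return rng.poisson(expected_total * abundance)


def _sequence(weights: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial read counts proportional to nonnegative weights."""
    total = weights.sum()
    if total == 0:
        return np.zeros_like(weights, dtype=np.int64)
    return rng.multinomial(depth, weights / total)


def simulate_rumen_and_cohort(
    truth: SyntheticTruth,
    params: SimulationParams,
    rng_rumen: np.random.Generator | None = None,
    rng_cohort: np.random.Generator | None = None,
):
    """Sequence the original sample, its dilutions, and the cohort.

    For dilution exponent d (0 = undiluted) the sequenced aliquot contains
    Poisson(inoculum_cells * 10^-d * abundance_t) cells of taxon t, and
    reads are multinomial over the cells present.  Cohort animals share
    the ecosystem-level abundance vector: each animal's log abundances are
    the focal animal's plus independent Normal(0, cohort_log_abundance_sigma)
    deviations, renormalized — so core taxa stay core and the rare
    biosphere stays rare across the herd.

    Returns ``(counts, metadata, flagged)`` where ``flagged`` lists samples
    emitted with all-zero counts (a fully extinguished aliquot).
    """
    if rng_rumen is None or rng_cohort is None:
        streams = params.substreams()
        rng_rumen = rng_rumen or streams["rumen"]
        rng_cohort = rng_cohort or streams["cohort"]
    rows, meta_rows, flagged = [], [], []
    for d in (0, *params.dilution_exponents):
        cells = poisson_cells(truth.abundance, params.inoculum_cells * 10.0 ** -d, rng_rumen)
        reads = _sequence(cells.astype(float), params.read_depth, rng_rumen)
        sample_id = f"rumen_d{d}"
        if reads.sum() == 0:
            flagged.append(sample_id)
        rows.append((sample_id, reads))
        meta_rows.append((sample_id, "rumen", "none", d, 1))
    for i in range(1, params.n_cohort_samples + 1):
        shift = rng_cohort.normal(
            0.0, params.cohort_log_abundance_sigma, params.n_taxa
        )
        weights = truth.abundance * np.exp(shift)
        reads = _sequence(weights, params.read_depth, rng_cohort)
        sample_id = f"cohort_{i:02d}"
        rows.append((sample_id, reads))
        meta_rows.append((sample_id, "cohort", "none", 0, 1))
    return rows, meta_rows, flagged


def simulate_plates(
    truth: SyntheticTruth,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
):
    """Plate each dilution in replicate on each medium and sequence the plates.

    Founders of taxon t on plate (d, medium, rep) are
    Poisson(inoculum_cells * 10^-d * abundance_t * cultivability(t, medium)).
    The plate is scraped whole, so its sequenced composition is
    proportional to founders * per-taxon growth factor.  Plates with zero
    founders are emitted as zero-count samples and flagged (empty plates).
    """
    if rng is None:
        rng = params.substreams()["plates"]
    rows, meta_rows, flagged = [], [], []
    for d in params.dilution_exponents:
        for medium in params.media:
            for rep in range(1, params.replicates + 1):
                rate = (
                    params.inoculum_cells
                    * 10.0 ** -d
                    * truth.abundance
                    * truth.cultivability[medium]
                )
                founders = rng.poisson(rate)
                weights = founders * truth.growth_factor
                reads = _sequence(weights, params.read_depth, rng)
                sample_id = f"plate_d{d}_{medium}_r{rep}"
                if founders.sum() == 0:
                    flagged.append(sample_id)
                rows.append((sample_id, reads))
                meta_rows.append((sample_id, "plate", medium, d, rep))
    return rows, meta_rows, flagged


def simulate_experiment(params: SimulationParams) -> ExperimentBundle:
    """Compose tree, truth, rumen series, plates, and cohort into one bundle.

    With default parameters the bundle holds 1 original + 6 dilution + 24
    plate + 38 cohort = 69 sequenced samples.  Byte-identical given the
    same seed.
    """
    streams = params.substreams()
    truth = simulate_truth(params)
    r_rows, r_meta, r_flag = simulate_rumen_and_cohort(
        truth, params, rng_rumen=streams["rumen"], rng_cohort=streams["cohort"]
    )
    p_rows, p_meta, p_flag = simulate_plates(truth, params, rng=streams["plates"])
    # order samples: rumen series, plates, cohort
    rumen_rows = [r for r in r_rows if r[0].startswith("rumen")]
    cohort_rows = [r for r in r_rows if r[0].startswith("cohort")]
    all_rows = rumen_rows + p_rows + cohort_rows
    counts = pd.DataFrame(
        np.vstack([reads for _, reads in all_rows]).astype(np.int64),
        index=[sid for sid, _ in all_rows],
        columns=truth.taxon_ids,
    )
    meta = pd.DataFrame(
        [m for m in r_meta if m[0].startswith("rumen")]
        + p_meta
        + [m for m in r_meta if m[0].startswith("cohort")],
        columns=["sample_id", "source", "medium", "dilution_exponent", "replicate"],
    )
    return ExperimentBundle(
        truth=truth,
        table=OtuTable(counts, validate=False),
        metadata=validate_metadata(meta),
        flagged=r_flag + p_flag,
    )


# ---------------------------------------------------------------------------
# truth-side summaries


def true_cultivable_fraction(bundle: ExperimentBundle, params: SimulationParams) -> float:
    """Fraction of rumen-detected taxa whose cultivability clears detectability.

    A rumen-detected taxon counts as truly cultivable when its best-medium
    cultivability exceeds 1 / (expected cells of that taxon in the least
    diluted plated aliquot), i.e. when at least one founder is expected on
    some plate.  Used to check that the pipeline's estimated cultivable
    fraction tracks the simulated truth.
    """
    from .core import rumen_sample_ids

    rumen_ids = rumen_sample_ids(bundle.metadata)
    detected = (bundle.table.data.loc[rumen_ids] > 0).any(axis=0)
    taxa = [t for t in bundle.truth.taxon_ids if detected.get(t, False)]
    if not taxa:
        return 0.0
    idx = {t: i for i, t in enumerate(bundle.truth.taxon_ids)}
    d_min = min(params.dilution_exponents)
    best = np.maximum.reduce(
        [bundle.truth.cultivability[m] for m in params.media]
    )
    n_cultivable = 0
    for t in taxa:
        i = idx[t]
        expected_cells = params.inoculum_cells * 10.0 ** -d_min * bundle.truth.abundance[i]
        if expected_cells > 0 and best[i] > 1.0 / expected_cells:
            n_cultivable += 1
    return n_cultivable / len(taxa)


# ---------------------------------------------------------------------------
# output


def write_bundle(bundle: ExperimentBundle, out_dir: str | Path) -> None:
    """Write otu_table.tsv, metadata.tsv, tree.nwk and truth.json."""
    from .core import write_metadata, write_otu_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_otu_table(bundle.table, out / "otu_table.tsv")
    write_metadata(bundle.metadata, out / "metadata.tsv")
    (out / "tree.nwk").write_text(bundle.truth.newick + "\n", encoding="utf-8")
    truth = bundle.truth
    payload = {
        "taxon_ids": truth.taxon_ids,
        "abundance": dict(zip(truth.taxon_ids, truth.abundance.tolist())),
        "liability": dict(zip(truth.taxon_ids, truth.liability.tolist())),
        "cultivability": {
            medium: dict(zip(truth.taxon_ids, probs.tolist()))
            for medium, probs in truth.cultivability.items()
        },
        "growth_factor": dict(zip(truth.taxon_ids, truth.growth_factor.tolist())),
        "flagged_samples": bundle.flagged,
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
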