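"""Ground-truthed synthetic fixtures for the aging-transcriptome pipeline.

Emulates the inputs the analysis assumes: a grouped count matrix with
multiplicative planted fold changes and multiplicative (log-normal) noise,
a pair of partially overlapping interaction "database" files in the two
supported dialects with a planted hub gene, and GMT annotation sets.

The default group sizes (8/6/3) mirror a young/aged/very-aged design; the
planted effect multiplies the group mean of selected genes in every aged
group, half of them up (x effect_fc) and half down (/ effect_fc).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio


class ConfigError(ValueError):
    """A simulation configuration violated its invariants."""


DEFAULT_GROUP_NAMES = ("3M", "24M", "29M")


@dataclass
class SimConfig:
    """Parameters of the expression-matrix simulator.

    noise_cv is the coefficient of variation of the mean-preserving
    log-normal multiplier applied to every expected count.
    """

    n_genes: int = 1000
    group_sizes: tuple[int, ...] = (8, 6, 3)
    de_fraction: float = 0.05
    effect_fc: float = 4.0
    noise_cv: float = 0.2
    baseline_mean_range: tuple[float, float] = (20.0, 500.0)
    length_range_bp: tuple[int, int] = (500, 5000)
    seed: int = 0
    group_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if any(g <= 0 for g in self.group_sizes):
            raise ConfigError("group sizes must be positive")
        if len(self.group_sizes) < 2:
            raise ConfigError("need at least two groups for a contrast")
        if not 0 < self.de_fraction < 1:
            raise ConfigError("de_fraction must lie in (0, 1)")
        if self.effect_fc < 1:
            raise ConfigError("effect_fc must be >= 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        for name, (lo, hi) in (
            ("baseline_mean_range", self.baseline_mean_range),
            ("length_range_bp", self.length_range_bp),
        ):
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must be ordered and positive")
        names = self.group_names or DEFAULT_GROUP_NAMES[: len(self.group_sizes)]
        if len(names) != len(self.group_sizes):
            raise ConfigError("group_names must match group_sizes in length")
        self.group_names = tuple(names)


@dataclass
class NetSimConfig:
    """Parameters of the interaction-database simulator.

    The planted hub is wired to exactly hub_target_count partners drawn
    from partner_pool (falling back to the background genes); genes in
    excluded_genes are guaranteed to appear in no interaction row, which
    plants recoverable singletons.
    """

    n_background_genes: int = 200
    edge_density: float = 0.02
    hub_symbol: str = "Ywhae"
    hub_target_count: int = 10
    db_overlap_fraction: float = 0.5
    taxid: str = "10090"
    seed: int = 0
    background_genes: tuple[str, ...] | None = None
    partner_pool: tuple[str, ...] | None = None
    excluded_genes: tuple[str, ...] = ()
    cross_species_rows: int = 0

    def __post_init__(self) -> None:
        if self.n_background_genes <= 0:
            raise ConfigError("n_background_genes must be positive")
        if not 0 <= self.edge_density < 1:
            raise ConfigError("edge_density must lie in [0, 1)")
        if self.hub_target_count < 0:
            raise ConfigError("hub_target_count must be >= 0")
        if not 0 <= self.db_overlap_fraction <= 1:
            raise ConfigError("db_overlap_fraction must lie in [0, 1]")
        if self.cross_species_rows < 0:
            raise ConfigError("cross_species_rows must be >= 0")


@dataclass
class SimTruth:
    """Everything the generator planted, for downstream recovery checks."""

    de_genes_up: dict[str, float] = field(default_factory=dict)
    de_genes_down: dict[str, float] = field(default_factory=dict)
    hub_symbol: str | None = None
    hub_partners: frozenset[str] = frozenset()
    singleton_genes: frozenset[str] = frozenset()
    edge_set: frozenset[tuple[str, str]] = frozenset()
    annotation_membership: dict[str, frozenset[str]] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "de_genes_up": self.de_genes_up,
            "de_genes_down": self.de_genes_down,
            "hub_symbol": self.hub_symbol,
            "hub_partners": sorted(self.hub_partners),
            "singleton_genes": sorted(self.singleton_genes),
            "edge_set": sorted(list(pair) for pair in self.edge_set),
            "annotation_membership": {
                t: sorted(g) for t, g in self.annotation_membership.items()
            },
        }


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(config: SimConfig) -> tuple[fio.CountMatrix, SimTruth]:
    """Simulate a grouped count matrix with planted multiplicative effects.

    Counts are drawn as round(mean * m) where the mean is an integer gene
    baseline (scaled by effect_fc, up or down, in every aged group for
    planted genes) and m is a mean-one log-normal multiplier with the
    configured coefficient of variation. With noise_cv = 0 the emitted
    counts equal the expected means exactly whenever they are integral.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    lengths = rng.integers(
        config.length_range_bp[0], config.length_range_bp[1] + 1, size=config.n_genes
    )
    baselines = rng.integers(
        int(config.baseline_mean_range[0]),
        int(config.baseline_mean_range[1]) + 1,
        size=config.n_genes,
    ).astype(float)

    n_de = int(round(config.de_fraction * config.n_genes))
    if n_de < 1:
        warnings.warn("de_fraction * n_genes < 1: no genes planted", stacklevel=2)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    n_up = (n_de + 1) // 2
    up_idx = np.sort(de_idx[:n_up])
    down_idx = np.sort(de_idx[n_up:])

    samples: list[str] = []
    group_of: dict[str, str] = {}
    for gname, gsize in zip(config.group_names, config.group_sizes):
        for i in range(1, gsize + 1):
            sid = f"{gname}_s{i}"
            samples.append(sid)
            group_of[sid] = gname

    # expected means: gene x sample; aged groups = every group after the first
    means = np.tile(baselines[:, None], (1, len(samples)))
    aged_cols = [j for j, s in enumerate(samples) if group_of[s] != config.group_names[0]]
    means[np.ix_(up_idx, aged_cols)] *= config.effect_fc
    means[np.ix_(down_idx, aged_cols)] /= config.effect_fc

    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        mult = rng.lognormal(-sigma**2 / 2, sigma, size=means.shape)
        counts = np.rint(means * mult).astype(int)
    else:
        counts = np.rint(means).astype(int)
    counts = np.maximum(counts, 0)

    cm = fio.CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_length_bp=pd.Series(lengths, index=genes),
        group_of=group_of,
    )
    truth = SimTruth(
        de_genes_up={genes[i]: float(config.effect_fc) for i in up_idx},
        de_genes_down={genes[i]: float(1.0 / config.effect_fc) for i in down_idx},
    )
    return cm, truth


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------


def simulate_interactome(
    config: NetSimConfig, out_dir: str | Path
) -> tuple[Path, Path, SimTruth]:
    """Simulate an interactome and emit it as two overlapping database files.

    Returns paths of the BioGRID-dialect file and the PSI-MITAB file plus
    the planted truth. The union of the two files' edge sets equals the
    simulated graph; a db_overlap_fraction share of edges appears in both.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.background_genes is not None:
        if len(config.background_genes) < config.n_background_genes:
            raise ConfigError("background_genes shorter than n_background_genes")
        background = list(config.background_genes[: config.n_background_genes])
    else:
        background = _gene_ids(config.n_background_genes)
    excluded = {fio.canonical_symbol(g) for g in config.excluded_genes}
    wired = [g for g in background if fio.canonical_symbol(g) not in excluded]

    pool = [
        g
        for g in (config.partner_pool if config.partner_pool is not None else wired)
        if fio.canonical_symbol(g) not in excluded
        and fio.canonical_symbol(g) != fio.canonical_symbol(config.hub_symbol)
    ]
    if config.hub_target_count > len(pool):
        raise ConfigError(
            f"hub_target_count={config.hub_target_count} exceeds partner pool "
            f"of {len(pool)} genes"
        )

    edges: set[tuple[str, str]] = set()
    n = len(wired)
    if config.edge_density > 0 and n > 1:
        # Bernoulli over all unordered background pairs
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < config.edge_density
        for i, j in zip(iu[mask], ju[mask]):
            edges.add(fio.canonical_pair(wired[i], wired[j]))
    partners = [pool[i] for i in rng.choice(len(pool), size=config.hub_target_count,
                                            replace=False)] if config.hub_target_count else []
    # the hub appears only through its planted edges, keeping its degree exact
    edges = {e for e in edges
             if fio.canonical_symbol(config.hub_symbol) not in e}
    for p in partners:
        edges.add(fio.canonical_pair(config.hub_symbol, p))

    edge_list = sorted(edges)
    order = rng.permutation(len(edge_list))
    n_both = int(round(config.db_overlap_fraction * len(edge_list)))
    in_a: list[tuple[str, str]] = []
    in_b: list[tuple[str, str]] = []
    for rank, idx in enumerate(order):
        e = edge_list[idx]
        if rank < n_both:
            in_a.append(e)
            in_b.append(e)
        elif rng.random() < 0.5:
            in_a.append(e)
        else:
            in_b.append(e)

    def rec(pair: tuple[str, str], source: str) -> fio.InteractionRecord:
        # stable digest, not hash(): pubmed ids must not vary across processes
        digest = hashlib.sha256("|".join(pair).encode()).hexdigest()
        return fio.InteractionRecord(
            symbol_a=pair[0],
            symbol_b=pair[1],
            taxid_a=config.taxid,
            taxid_b=config.taxid,
            source_db=source,
            evidence="two hybrid" if source == fio.BIOGRID else "psi-mi:affinity",
            pubmed_id=str(10000000 + int(digest[:6], 16) % 1000000),
        )

    recs_a = [rec(e, fio.BIOGRID) for e in sorted(in_a)]
    recs_b = [rec(e, fio.INTACT) for e in sorted(in_b)]
    # optional cross-species contamination, exercised by the species filter
    other_tax = "9606" if config.taxid != "9606" else "10090"
    for i in range(config.cross_species_rows):
        a, b = rng.choice(len(wired), size=2, replace=False)
        r = fio.InteractionRecord(
            symbol_a=wired[a], symbol_b=wired[b],
            taxid_a=config.taxid, taxid_b=other_tax,
            source_db=fio.BIOGRID if i % 2 == 0 else fio.INTACT,
            evidence="cross-species",
        )
        (recs_a if i % 2 == 0 else recs_b).append(r)

    biogrid_path = out_dir / "interactions_biogrid.txt"
    mitab_path = out_dir / "interactions_intact.mitab"
    fio.write_biogrid_tab(recs_a, biogrid_path)
    fio.write_mitab(recs_b, mitab_path)

    truth = SimTruth(
        hub_symbol=config.hub_symbol,
        hub_partners=frozenset(fio.canonical_symbol(p) for p in partners),
        singleton_genes=frozenset(excluded),
        edge_set=frozenset(edge_list),
    )
    return biogrid_path, mitab_path, truth


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    directory: str | Path,
    sim_config: SimConfig | None = None,
    net_config: NetSimConfig | None = None,
    n_planted_singletons: int = 3,
) -> dict:
    """Emit a complete, internally consistent fixture bundle.

    The interaction files reuse the expression gene universe; the planted
    hub is wired preferentially to up-regulated planted genes, which also
    populate an immune-response-like annotation term, so seeded subnetwork
    extraction on the bundle is nontrivial. A few annotated up-genes are
    kept out of the interactome entirely as planted singletons.

    Returns the manifest (also written to ``manifest.json``) listing the
    eight emitted files with SHA-256 checksums and the seeds used.
    """
    directory = Path(directory)
    if not directory.parent.exists():
        raise FileNotFoundError(f"cannot create bundle under missing path: {directory.parent}")
    directory.mkdir(parents=True, exist_ok=True)
    sim_config = sim_config or SimConfig()
    net_config = net_config or NetSimConfig()

    cm, expr_truth = simulate_expression(sim_config)
    counts_path = directory / "counts.tsv"
    lengths_path = directory / "lengths.tsv"
    groups_path = directory / "groups.tsv"
    fio.write_count_matrix(cm, counts_path)
    with open(lengths_path, "w") as fh:
        fh.write("gene_id\tlength_bp\n")
        for g, length in cm.gene_length_bp.items():
            fh.write(f"{g}\t{length}\n")
    fio.write_group_labels(cm.group_of, groups_path)

    up_genes = sorted(expr_truth.de_genes_up)
    down_genes = sorted(expr_truth.de_genes_down)
    rng = np.random.default_rng(sim_config.seed + 1)
    null_genes = sorted(set(cm.gene_ids) - set(up_genes) - set(down_genes))
    extras = [null_genes[i] for i in rng.choice(len(null_genes), size=10, replace=False)]

    # keep enough up-genes out of the singleton set to wire the hub
    n_planted_singletons = min(
        n_planted_singletons, max(len(up_genes) - net_config.hub_target_count, 0)
    )
    singletons = tuple(up_genes[:n_planted_singletons])
    immune_genes = list(up_genes) + extras[:5]
    hippo_genes = list(down_genes) + extras[5:] + up_genes[-3:]
    annotations = fio.AnnotationCollection()
    annotations.add("immune_response", "immune-response-like planted term", immune_genes)
    annotations.add(
        "hippocampal_development", "hippocampal-development-like planted term", hippo_genes
    )
    gmt_path = directory / "annotations.gmt"
    fio.write_gmt(annotations, gmt_path)

    # hub partners come preferentially from annotated up-genes, topped up
    # from unplanted genes when the pool is too small
    partner_pool = [g for g in up_genes if g not in singletons]
    if len(partner_pool) < net_config.hub_target_count:
        partner_pool += [g for g in null_genes if g not in extras]
    partner_pool = tuple(partner_pool)
    net_config_used = NetSimConfig(
        n_background_genes=min(net_config.n_background_genes, len(cm.gene_ids)),
        edge_density=net_config.edge_density,
        hub_symbol=net_config.hub_symbol,
        hub_target_count=net_config.hub_target_count,
        db_overlap_fraction=net_config.db_overlap_fraction,
        taxid=net_config.taxid,
        seed=net_config.seed,
        background_genes=tuple(cm.gene_ids),
        partner_pool=partner_pool,
        excluded_genes=singletons,
        cross_species_rows=net_config.cross_species_rows,
    )
    biogrid_path, mitab_path, net_truth = simulate_interactome(net_config_used, directory)

    truth = SimTruth(
        de_genes_up=expr_truth.de_genes_up,
        de_genes_down=expr_truth.de_genes_down,
        hub_symbol=net_truth.hub_symbol,
        hub_partners=net_truth.hub_partners,
        singleton_genes=net_truth.singleton_genes,
        edge_set=net_truth.edge_set,
        annotation_membership={
            t: genes for t, (_, genes) in annotations.terms.items()
        },
    )
    truth_path = directory / "truth.json"
    fio.write_json(truth.to_json(), truth_path)

    config_path = directory / "config.json"
    fio.write_json(
        {
            "sim_config": {**sim_config.__dict__},
            "net_config": {**net_config_used.__dict__},
        },
        config_path,
    )

    files = {
        "counts": counts_path,
        "lengths": lengths_path,
        "groups": groups_path,
        "biogrid": biogrid_path,
        "mitab": mitab_path,
        "annotations": gmt_path,
        "truth": truth_path,
        "config": config_path,
    }
    manifest = {
        "files": {
            name: {"path": p.name, "sha256": _sha256(p)} for name, p in files.items()
        },
        "seeds": {"expression": sim_config.seed, "interactome": net_config_used.seed},
    }
    fio.write_json(manifest, directory / "manifest.json")
    return manifest
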