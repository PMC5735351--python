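"""End-to-end orchestration: simulate -> normalize -> call DEGs -> overlap
algebra -> merge interactome -> seeded subnetwork -> hubs -> enrichment ->
cross-experiment comparison, with a reproducible JSON run manifest.

Every stage is also runnable standalone through the library functions (or
the CLI subcommands); the pipeline only sequences them and records
provenance. Manifests contain no timestamps, so reruns with identical
config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import expression as expr
from . import interactome as ita
from . import io as fio
from . import netanalysis as na
from . import synthetic as syn

__version__ = "0.1.0"

PRESETS = {name: th for name, th in expr.THRESHOLD_PRESETS.items()}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Normalized run configuration with all defaults filled in."""

    out_dir: str = "agingnet_run"
    # inputs; when counts is None the synthetic bundle is generated
    counts: str | None = None
    lengths: str | None = None
    groups: str | None = None
    biogrid: str | None = None
    mitab: str | None = None
    gmt: str | None = None
    # analysis parameters
    preset: str | None = "gse61915"
    fc_up: float | None = None
    fc_down: float | None = None
    p_max: float | None = None
    taxid: str = "10090"
    ref_group: str = "3M"
    alt_groups: tuple[str, ...] = ("24M", "29M")
    seed_term: str = "immune_response"
    mode: str = "SEEDS_ARE_DEGS"
    depth: int = 1
    enrich_method: str = "hypergeometric"
    hub_k: int = 10
    seed: int = 0

    def thresholds(self) -> expr.DEGThresholds:
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ConfigError(
                    f"unknown preset {self.preset!r}; valid presets: "
                    f"{', '.join(sorted(PRESETS))}"
                )
            base = PRESETS[self.preset]
        else:
            base = expr.DEGThresholds()
        return expr.DEGThresholds(
            fc_up=self.fc_up if self.fc_up is not None else base.fc_up,
            fc_down=self.fc_down if self.fc_down is not None else base.fc_down,
            p_max=self.p_max if self.p_max is not None else base.p_max,
            test=base.test,
            value_scale=base.value_scale,
            pseudocount=base.pseudocount,
        )


def validate_config(source: str | Path | dict | None) -> PipelineConfig:
    """Load and normalize a YAML/JSON pipeline configuration.

    Unknown keys and unknown preset names are rejected; an empty document
    yields all defaults.
    """
    if source is None:
        doc: dict = {}
    elif isinstance(source, dict):
        doc = dict(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
    if "alt_groups" in doc:
        doc["alt_groups"] = tuple(doc["alt_groups"])
    cfg = PipelineConfig(**doc)
    cfg.thresholds()  # validates the preset and threshold sanity
    if cfg.depth not in (1, 2):
        raise ConfigError("depth must be 1 or 2")
    if cfg.mode not in (m.value for m in na.SeedMode):
        raise ConfigError(f"unknown mode {cfg.mode!r}")
    if cfg.enrich_method not in (enr.HYPERGEOMETRIC, enr.EASE):
        raise ConfigError(f"unknown enrichment method {cfg.enrich_method!r}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; return (and write) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        if config.counts is None:
            stage = "simulate"
            bundle_dir = out / "bundle"
            syn.write_fixture_bundle(
                bundle_dir,
                syn.SimConfig(seed=config.seed),
                syn.NetSimConfig(seed=config.seed),
            )
            counts, lengths, groups = (
                bundle_dir / "counts.tsv",
                bundle_dir / "lengths.tsv",
                bundle_dir / "groups.tsv",
            )
            biogrid = bundle_dir / "interactions_biogrid.txt"
            mitab = bundle_dir / "interactions_intact.mitab"
            gmt = bundle_dir / "annotations.gmt"
        else:
            counts = Path(config.counts)
            lengths = Path(config.lengths) if config.lengths else None
            groups = Path(config.groups) if config.groups else None
            biogrid = Path(config.biogrid) if config.biogrid else None
            mitab = Path(config.mitab) if config.mitab else None
            gmt = Path(config.gmt) if config.gmt else None
        for name, p in (("counts", counts), ("groups", groups), ("biogrid", biogrid),
                        ("mitab", mitab), ("gmt", gmt)):
            if p is not None and not p.exists():
                raise PipelineError("inputs", f"missing {name} file: {p}")

        stage = "read_counts"
        cm = fio.read_count_matrix(counts, groups, lengths)

        stage = "rpkm"
        em = expr.compute_rpkm(cm)

        stage = "deg"
        thresholds = config.thresholds()
        contrasts = [
            expr.call_degs(em, config.ref_group, alt, thresholds)
            for alt in config.alt_groups
        ]
        for c in contrasts:
            p = out / f"deg_{c.label.replace('/', '_vs_')}.tsv"
            fio.write_gene_table(c.table.reset_index(names="gene_id"), p)
            outputs[f"deg:{c.label}"] = p

        stage = "venn"
        up_sets = {c.label: c.up_genes for c in contrasts}
        down_sets = {c.label: c.down_genes for c in contrasts}
        venn_up = expr.venn_partition(up_sets, direction="UP")
        venn_down = expr.venn_partition(down_sets, direction="DOWN")
        venn_path = out / "venn.json"
        fio.write_json(
            {
                d: {
                    "+".join(sorted(k)): sorted(v)
                    for k, v in part.regions.items()
                }
                for d, part in (("UP", venn_up), ("DOWN", venn_down))
            },
            venn_path,
        )
        outputs["venn"] = venn_path
        consistent_up = venn_up.intersection(*venn_up.labels)
        consistent_down = venn_down.intersection(*venn_down.labels)

        stage = "merge_interactome"
        records: list[fio.InteractionRecord] = []
        if biogrid is not None:
            records += fio.read_biogrid_tab(biogrid)
        if mitab is not None:
            mrecs, _ = fio.read_mitab(mitab)
            records += mrecs
        records, filter_report = ita.filter_species(records)
        net = ita.merge_interactomes(records, taxid=config.taxid)
        net_path = out / "interactome.sif"
        fio.write_sif(net, net_path)
        outputs["interactome"] = net_path
        report_path = out / "merge_report.json"
        fio.write_json(
            {**ita.merge_report(net), "species_filter": filter_report.__dict__},
            report_path,
        )
        outputs["merge_report"] = report_path

        stage = "subnetwork"
        annotations = fio.read_gmt(gmt)
        if config.seed_term not in annotations.terms:
            raise PipelineError(
                "subnetwork", f"seed term {config.seed_term!r} not in {gmt}"
            )
        term_genes = annotations.genes(config.seed_term)
        mode = na.SeedMode(config.mode)
        if mode == na.SeedMode.SEEDS_ARE_DEGS:
            seeds = term_genes & frozenset(
                fio.canonical_symbol(g) for g in consistent_up
            )
            spec = na.SeedSpec(seed_genes=seeds or term_genes, mode=mode,
                               depth=config.depth)
        else:
            universe = frozenset(fio.canonical_symbol(g)
                                 for g in consistent_up | consistent_down)
            spec = na.SeedSpec(seed_genes=term_genes, mode=mode,
                               deg_universe=universe, depth=config.depth)
        subnet = na.extract_subnetwork(net, spec)
        sub_sif = out / "subnetwork.sif"
        sub_gml = out / "subnetwork.graphml"
        fio.write_sif(subnet.graph, sub_sif)
        fio.write_graphml(subnet.graph, sub_gml)
        outputs["subnetwork_sif"] = sub_sif
        outputs["subnetwork_graphml"] = sub_gml

        stage = "hubs"
        ranking = na.degree_ranking(subnet, k=config.hub_k)
        hubs_path = out / "hubs.tsv"
        fio.write_gene_table(
            pd.DataFrame(ranking.entries, columns=["gene", "degree"]), hubs_path
        )
        outputs["hubs"] = hubs_path

        stage = "singletons"
        singles = na.find_singletons(net, spec)
        singles_path = out / "singletons.json"
        fio.write_json(sorted(singles), singles_path)
        outputs["singletons"] = singles_path

        stage = "enrich"
        background = frozenset(fio.canonical_symbol(g) for g in cm.gene_ids)
        query = frozenset(fio.canonical_symbol(g) for g in consistent_up) & background
        results = (
            enr.enrich(query, annotations, background, method=config.enrich_method)
            if query
            else []
        )
        enrich_path = out / "enrichment.tsv"
        fio.write_gene_table(
            pd.DataFrame([r.__dict__ for r in results]), enrich_path
        )
        outputs["enrichment"] = enrich_path

        stage = "compare"
        compare_path = out / "compare.json"
        if consistent_up and consistent_down:
            report = expr.compare_experiments(
                consistent_up, consistent_down, universe=background
            )
            payload = {
                "n_overlap": report.n_overlap,
                "overlap": sorted(report.intersection),
                "jaccard": report.jaccard,
                "p_hypergeometric": report.p_hypergeometric,
            }
        else:
            payload = {"n_overlap": 0, "overlap": [], "jaccard": 0.0,
                       "p_hypergeometric": None}
        fio.write_json(payload, compare_path)
        outputs["compare"] = compare_path

    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "tool": "agingnet",
        "version": __version__,
        "config": {**asdict(config), "alt_groups": list(config.alt_groups)},
        "outputs": {
            name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for name, p in outputs.items()
        },
    }
    fio.write_json(manifest, out / "manifest.json")
    return manifest
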