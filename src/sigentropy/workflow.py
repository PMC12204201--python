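"""Command-line orchestration of the entropy-stability protocol.

Subcommands mirror the analysis stages: ``simulate`` (synthetic study
system), ``compute`` (per-sample entropy rates), ``perturb`` (Case-Study-1
style perturbation sweep), ``score`` (edge-reliability tables), ``filter``
(threshold filtering), ``compare`` (two-group significance), and
``stabilise`` (Case-Study-2 style evaluation grid).  Every command writes
a JSON run manifest (inputs + SHA-256 hashes, parameters, seed, package
version) sufficient to reproduce its output bit for bit.

A YAML config file may supply any option; command-line flags override
config values.  The recommended stabilisation preset follows the
protocol's conclusion: STRING-score correction at threshold 0.6 with the
non-equilibrium measure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import click
import pandas as pd
import yaml

from . import __version__
from .correction import (
    filter_network,
    information_content,
    load_string_scores,
    read_annotations,
    read_obo,
    read_scores,
    semantic_edge_scores,
    topological_scores,
    write_scores,
)
from .entropy import entropy_table, integrate, read_expression, write_entropy_table
from .network import read_network, read_mapping_table, write_edgelist
from .perturb import KINDS, perturbation_sweep
from .stats import LabelledSystem, compare_groups, evaluation_grid
from .synthdata import (
    SyntheticSpec,
    generate_expression,
    generate_network,
    generate_ontology,
    generate_score_table,
    write_ontology_obo,
)

logger = logging.getLogger("sigentropy")

DEFAULT_THRESHOLD = 0.6  # recommended STRING-filter preset
SWEEP_COLUMNS = ["kind", "level", "replicate", "sample", "sr_neq", "sr_eq", "lcc_nodes", "lcc_edges", "gamma"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, command: str, params: dict, inputs: list[Path]) -> None:
    manifest = {
        "command": command,
        "package_version": __version__,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "inputs": {str(p): _sha256(p) for p in inputs if p is not None and Path(p).exists()},
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{command}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_config(path: str | None) -> dict:
    if not path:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise click.ClickException("config must be a YAML mapping")
    return cfg


def _opt(ctx_cfg: dict, section: str, key: str, cli_value, default=None):
    """CLI flag > config-file value > default."""
    if cli_value is not None:
        return cli_value
    sect = ctx_cfg.get(section, {})
    if isinstance(sect, dict) and key in sect:
        return sect[key]
    if key in ctx_cfg:
        return ctx_cfg[key]
    return default


@click.group()
@click.option("--config", type=click.Path(exists=True, dir_okay=False), default=None, help="YAML config file.")
@click.option("--seed", type=int, default=None, help="Global random seed.")
@click.option("--log-level", default=None, type=click.Choice(["DEBUG", "INFO", "WARNING", "ERROR"]))
@click.pass_context
def main(ctx: click.Context, config: str | None, seed: int | None, log_level: str | None) -> None:
    """Signalling-entropy rates on interaction networks, with perturbation
    analysis and reliability-based network correction."""
    cfg = _load_config(config)
    level = log_level or cfg.get("log_level", "INFO")
    logging.basicConfig(level=getattr(logging, level), format="%(levelname)s %(name)s: %(message)s")
    ctx.obj = {"config": cfg, "seed": seed if seed is not None else int(cfg.get("seed", 0))}


def _read_net(path: str, fmt: str, mapping: str | None):
    m = read_mapping_table(mapping) if mapping else None
    return read_network(path, format=fmt, mapping=m)


@main.command()
@click.option("--network", "network_path", required=True, type=click.Path(exists=True))
@click.option("--format", "fmt", default="edgelist", type=click.Choice(["edgelist", "sif", "string_links"]))
@click.option("--mapping", default=None, type=click.Path(exists=True), help="Two-column id mapping TSV.")
@click.option("--expression", required=True, type=click.Path(exists=True))
@click.option("--measures", default="neq,eq", help="Comma-separated subset of {neq,eq}.")
@click.option("--out", required=True, type=click.Path(), help="Output directory.")
@click.pass_context
def compute(ctx, network_path, fmt, mapping, expression, measures, out):
    """Per-sample entropy table from a network and an expression matrix."""
    try:
        net = _read_net(network_path, fmt, mapping)
        expr = read_expression(expression)
        system = integrate(net, expr)
        table = entropy_table(system, measures=tuple(m.strip() for m in measures.split(",")))
    except (ValueError, KeyError, OSError) as exc:
        raise click.ClickException(str(exc)) from exc
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_entropy_table(table, out_dir / "entropy.tsv")
    _write_manifest(
        out_dir,
        "compute",
        {"network": network_path, "format": fmt, "expression": expression, "measures": measures,
         "seed": ctx.obj["seed"]},
        [Path(network_path), Path(expression)] + ([Path(mapping)] if mapping else []),
    )
    click.echo(f"wrote {out_dir / 'entropy.tsv'} ({len(table)} samples)")


@main.command()
@click.option("--network", "network_path", required=True, type=click.Path(exists=True))
@click.option("--format", "fmt", default="edgelist", type=click.Choice(["edgelist", "sif", "string_links"]))
@click.option("--expression", required=True, type=click.Path(exists=True))
@click.option("--kinds", default=",".join(KINDS))
@click.option("--levels", default="0.1,0.2,0.3,0.4,0.5,0.6,0.7,0.8,0.9")
@click.option("--replicates", type=int, default=None)
@click.option("--measures", default="neq,eq")
@click.option("--out", required=True, type=click.Path())
@click.pass_context
def perturb(ctx, network_path, fmt, expression, kinds, levels, replicates, measures, out):
    """Perturbation sweep: entropy rates across kind x level x replicate.

    If the output table already exists, completed (kind, level, replicate)
    cells are skipped and the new rows appended."""
    cfg = ctx.obj["config"]
    replicates = int(_opt(cfg, "perturb", "replicates", replicates, 5))
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    sweep_path = out_dir / "sweep.tsv"
    skip: set[tuple[str, float, int]] = set()
    previous = None
    if sweep_path.exists():
        previous = pd.read_csv(sweep_path, sep="\t")
        skip = {
            (str(k), float(l), int(r))
            for k, l, r in previous[["kind", "level", "replicate"]].drop_duplicates().itertuples(index=False)
        }
        logger.info("resuming: %d completed cells found", len(skip))
    try:
        net = _read_net(network_path, fmt, None)
        expr = read_expression(expression)
        table = perturbation_sweep(
            net,
            expr,
            kinds=[k.strip() for k in kinds.split(",")],
            levels=[float(x) for x in levels.split(",")],
            replicates=replicates,
            seed=ctx.obj["seed"],
            measures=tuple(m.strip() for m in measures.split(",")),
            skip_cells=skip,
        )
    except (ValueError, KeyError, OSError) as exc:
        raise click.ClickException(str(exc)) from exc
    if previous is not None:
        table = pd.concat([previous, table], ignore_index=True)
    table = table.sort_values(["kind", "level", "replicate", "sample"]).reset_index(drop=True)
    table.to_csv(sweep_path, sep="\t", index=False, columns=SWEEP_COLUMNS, float_format="%.10g")
    _write_manifest(
        out_dir,
        "perturb",
        {"network": network_path, "expression": expression, "kinds": kinds, "levels": levels,
         "replicates": replicates, "measures": measures, "seed": ctx.obj["seed"]},
        [Path(network_path), Path(expression)],
    )
    click.echo(f"wrote {sweep_path} ({len(table)} rows)")


@main.command()
@click.option("--network", "network_path", required=True, type=click.Path(exists=True))
@click.option("--format", "fmt", default="edgelist", type=click.Choice(["edgelist", "sif", "string_links"]))
@click.option("--method", required=True,
              type=click.Choice(["jaccard", "dice", "invlog", "resnik", "lin", "jiang", "schlicker", "wang", "string"]))
@click.option("--ontology", default=None, type=click.Path(exists=True), help="OBO file (semantic methods).")
@click.option("--annotations", default=None, type=click.Path(exists=True), help="GAF or TSV (semantic methods).")
@click.option("--string-links", default=None, type=click.Path(exists=True), help="STRING links table (string method).")
@click.option("--out", required=True, type=click.Path())
@click.pass_context
def score(ctx, network_path, fmt, method, ontology, annotations, string_links, out):
    """Edge-reliability scores for a network."""
    try:
        net = _read_net(network_path, fmt, None)
        if method in {"jaccard", "dice", "invlog"}:
            scores = topological_scores(net, method)
        elif method == "string":
            if not string_links:
                raise click.ClickException("--string-links is required for method=string")
            scores = load_string_scores(string_links)
        else:
            if not ontology or not annotations:
                raise click.ClickException("--ontology and --annotations are required for semantic methods")
            ont = read_obo(ontology)
            ann = read_annotations(annotations, ont)
            ic = information_content(ont, ann)
            scores = semantic_edge_scores(net, ann, ic, ont, method)
    except (ValueError, KeyError, OSError) as exc:
        raise click.ClickException(str(exc)) from exc
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    score_path = out_dir / f"scores_{method}.tsv"
    write_scores(scores, score_path)
    _write_manifest(
        out_dir, "score",
        {"network": network_path, "method": method, "seed": ctx.obj["seed"]},
        [Path(p) for p in (network_path, ontology, annotations, string_links) if p],
    )
    click.echo(f"wrote {score_path} ({len(scores)} edges scored)")


@main.command(name="filter")
@click.option("--network", "network_path", required=True, type=click.Path(exists=True))
@click.option("--format", "fmt", default="edgelist", type=click.Choice(["edgelist", "sif", "string_links"]))
@click.option("--scores", "scores_path", required=True, type=click.Path(exists=True))
@click.option("--threshold", type=float, default=DEFAULT_THRESHOLD, show_default=True)
@click.option("--out", required=True, type=click.Path())
@click.pass_context
def filter_cmd(ctx, network_path, fmt, scores_path, threshold, out):
    """Filter a network by a reliability-score table at a threshold."""
    try:
        net = _read_net(network_path, fmt, None)
        scores = read_scores(scores_path)
        filtered, stats = filter_network(net, scores, threshold)
    except (ValueError, KeyError, OSError) as exc:
        raise click.ClickException(str(exc)) from exc
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_edgelist(filtered, out_dir / "filtered_edgelist.tsv")
    with open(out_dir / "filter_stats.json", "w") as fh:
        json.dump(stats.__dict__, fh, indent=2)
        fh.write("\n")
    _write_manifest(
        out_dir, "filter",
        {"network": network_path, "scores": scores_path, "threshold": threshold, "seed": ctx.obj["seed"]},
        [Path(network_path), Path(scores_path)],
    )
    click.echo(
        f"kept {stats.n_edges_after}/{stats.n_edges_before} edges at threshold {threshold:g}"
    )


@main.command()
@click.option("--entropy-table", "table_path", required=True, type=click.Path(exists=True),
              help="TSV from `compute` with an sr_neq or sr_eq column.")
@click.option("--labels", "labels_path", required=True, type=click.Path(exists=True),
              help="Two-column TSV sample -> class label (two classes).")
@click.option("--measure", default="sr_neq", type=click.Choice(["sr_neq", "sr_eq"]))
@click.option("--test", default="wilcoxon", type=click.Choice(["wilcoxon", "ttest"]))
@click.pass_context
def compare(ctx, table_path, labels_path, measure, test):
    """Two-group significance test on a per-sample entropy table."""
    try:
        table = pd.read_csv(table_path, sep="\t", index_col=0)
        labels = read_mapping_table(labels_path)
        groups = sorted(set(labels.values()))
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 classes, got {groups}")
        vals = {
            g: [table.loc[s, measure] for s in table.index if labels.get(str(s)) == g]
            for g in groups
        }
        res = compare_groups(vals[groups[0]], vals[groups[1]], test=test)
    except (ValueError, KeyError, OSError) as exc:
        raise click.ClickException(str(exc)) from exc
    click.echo(
        f"{groups[0]} (n={res.n_a}, median={res.median_a:.6g}) vs "
        f"{groups[1]} (n={res.n_b}, median={res.median_b:.6g}): "
        f"p={res.p_value:.4g} [{res.test}]"
    )


@main.command()
@click.option("--n-nodes", type=int, default=None)
@click.option("--n-samples", type=int, default=None)
@click.option("--classes", default="wildtype,dual_ko")
@click.option("--with-ontology", is_flag=True, default=False)
@click.option("--out", required=True, type=click.Path())
@click.pass_context
def simulate(ctx, n_nodes, n_samples, classes, with_ontology, out):
    """Generate a synthetic interactome + two-class expression (+ ontology)."""
    cfg = ctx.obj["config"]
    spec = SyntheticSpec(
        n_nodes=int(_opt(cfg, "simulate", "n_nodes", n_nodes, 500)),
        n_samples=int(_opt(cfg, "simulate", "n_samples", n_samples, 20)),
        seed=ctx.obj["seed"],
    )
    try:
        net = generate_network(spec)
        expr, labels = generate_expression(net, spec, classes=tuple(classes.split(",")))
    except ValueError as exc:
        raise click.ClickException(str(exc)) from exc
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_edgelist(net, out_dir / "network_edgelist.tsv")
    expr.values.to_csv(out_dir / "expression.tsv", sep="\t", float_format="%.8g")
    with open(out_dir / "labels.tsv", "w") as fh:
        for s, lab in labels.items():
            fh.write(f"{s}\t{lab}\n")
    if with_ontology:
        from .correction import write_annotations

        ont, ann = generate_ontology(seed=spec.seed, genes=sorted(net.nodes))
        write_ontology_obo(ont, out_dir / "ontology.obo")
        write_annotations(ann, out_dir / "annotations.tsv")
    _write_manifest(out_dir, "simulate", {"spec": spec.__dict__, "classes": classes}, [])
    click.echo(f"wrote synthetic system to {out_dir} ({net.n_nodes} nodes, {net.n_edges} edges)")


@main.command()
@click.option("--network", "network_paths", multiple=True, required=True,
              help="PIN as label=path (repeatable).")
@click.option("--format", "fmt", default="edgelist", type=click.Choice(["edgelist", "sif", "string_links"]))
@click.option("--expression", required=True, type=click.Path(exists=True))
@click.option("--labels", "labels_path", required=True, type=click.Path(exists=True))
@click.option("--dataset", default="dataset")
@click.option("--scores", "score_paths", multiple=True, help="Score table as method=path (repeatable).")
@click.option("--thresholds", default="0.1,0.2,0.3,0.4,0.5,0.6,0.7,0.8,0.9")
@click.option("--alpha", type=float, default=0.05, show_default=True)
@click.option("--repetitions", type=int, default=50, show_default=True)
@click.option("--out", required=True, type=click.Path())
@click.pass_context
def stabilise(ctx, network_paths, fmt, expression, labels_path, dataset, score_paths,
              thresholds, alpha, repetitions, out):
    """Evaluation grid: filtering thresholds vs significance stability."""
    try:
        expr = read_expression(expression)
        labels = read_mapping_table(labels_path)
        systems = []
        for item in network_paths:
            if "=" not in item:
                raise ValueError(f"--network expects label=path, got {item!r}")
            label, path = item.split("=", 1)
            systems.append(
                LabelledSystem(
                    dataset=dataset,
                    pin=label,
                    network=_read_net(path, fmt, None),
                    expression=expr,
                    classes=labels,
                )
            )
        corrections = []
        for item in score_paths:
            if "=" not in item:
                raise ValueError(f"--scores expects method=path, got {item!r}")
            method, path = item.split("=", 1)
            corrections.append(read_scores(path, method=method))
        grid, counts = evaluation_grid(
            systems,
            corrections,
            thresholds=[float(x) for x in thresholds.split(",")],
            alpha=alpha,
            repetitions=repetitions,
            seed=ctx.obj["seed"],
        )
    except (ValueError, KeyError, OSError) as exc:
        raise click.ClickException(str(exc)) from exc
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid.to_csv(out_dir / "grid.tsv", sep="\t", index=False, float_format="%.10g")
    summary = {
        "alpha": counts.alpha,
        "between_errors": {f"{p}|{m}": v for (p, m), v in sorted(counts.between_errors.items())},
        "within_errors": {f"{p}|{m}": v for (p, m), v in sorted(counts.within_errors.items())},
        "na_cells": {f"{p}|{m}": v for (p, m), v in sorted(counts.na_cells.items())},
        "n_cells": {f"{p}|{m}": v for (p, m), v in sorted(counts.n_cells.items())},
    }
    with open(out_dir / "error_counts.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_manifest(
        out_dir, "stabilise",
        {"networks": list(network_paths), "expression": expression, "labels": labels_path,
         "scores": list(score_paths), "thresholds": thresholds, "alpha": alpha,
         "repetitions": repetitions, "seed": ctx.obj["seed"]},
        [Path(expression), Path(labels_path)]
        + [Path(i.split("=", 1)[1]) for i in network_paths if "=" in i]
        + [Path(i.split("=", 1)[1]) for i in score_paths if "=" in i],
    )
    click.echo(f"wrote {out_dir / 'grid.tsv'} ({len(grid)} cells)")


if __name__ == "__main__":  # pragma: no cover
    main()
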