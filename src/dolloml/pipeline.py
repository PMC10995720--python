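"""End-to-end orchestration: generate or load inputs, run both
reconstruction engines, tally counts and gains/losses, and write a
replicate-level report bundle.

The bundle layout under ``outdir`` is::

    manifest.json                     run config, seeds, per-replicate status
    counts_by_node.tsv                long form: replicate x method x node
    rep<k>/orthogroups.tsv            synthetic mode only
    rep<k>/singletons.tsv
    rep<k>/truth.json
    rep<k>/matrix.tsv                 the binary input matrix
    rep<k>/<method>_nodes.tsv         per-node count/gains/losses/depth
    rep<k>/<method>_overestimation.tsv  when the true count is known
    rep<k>/ml_params.json             fitted kappa/alpha/logL

Internal nodes are reported by their stable post-order integer id plus the
lexicographically smallest tip label on each side ("a|b"), so outputs stay
comparable across tools that renumber nodes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import counting, dollo, ml_ancestral, phylo_io, synthetic_data
from .phylo_io import PresenceMatrix, RootedTree

logger = logging.getLogger("dolloml")

METHODS = ("dollo", "ml")


@dataclass
class RunConfig:
    """Configuration of one comparison run (CLI flags mirror these fields)."""

    mode: str = "synthetic"                # "synthetic" | "matrix"
    tree: str | None = None                # Newick path; default guide tree
    matrices: list[str] = field(default_factory=list)
    methods: tuple[str, ...] = METHODS
    n_replicates: int = 3
    n_families: int = 5000
    seq_length: int = 200
    rate_scalars: list[float] | None = None
    alpha_sites: float | None = None
    identity_threshold: float = synthetic_data.IDENTITY_THRESHOLD
    paralog_fraction: float = 0.05
    ml_free: tuple[str, ...] = ("kappa", "alpha", "branch_lengths")
    n_categories: int = 4
    fixed_branch_lengths: bool = False
    gain_loss_mode: str = "expected-difference"
    truth: int | None = None
    outdir: str = "dolloml_out"
    seed: int | None = None
    log_level: str = "INFO"
    write_states: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "matrix"):
            raise ValueError(f"unknown mode {self.mode!r}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires a seed")
        if self.mode == "matrix" and not self.matrices:
            raise ValueError("matrix mode requires at least one matrix file")


def node_names(tree: RootedTree) -> list[str]:
    """Stable display names: tips by label, internal nodes by the smallest
    tip label of each child subtree, joined with '|'."""
    tips = tree.subtree_tips()
    names = []
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            names.append(tree.labels[v])
        else:
            parts = sorted(min(tips[c]) for c in tree.children[v])
            names.append("|".join(parts[:2]))
    return names


def _load_matrix(path: str) -> PresenceMatrix:
    if str(path).endswith((".tsv", ".txt")):
        return phylo_io.read_matrix_tsv(path)
    return phylo_io.read_phylip_discrete(path)


def _resolve_tree(config: RunConfig) -> RootedTree:
    if config.tree is not None:
        tree = phylo_io.read_newick(config.tree)
    else:
        if config.mode == "matrix":
            raise ValueError("matrix mode requires a tree file")
        tree = synthetic_data.guide_tree(seed=config.seed)
    if not tree.is_binary():
        tree = phylo_io.resolve_polytomies(tree, seed=config.seed or 0)
    return tree


def run_compare(config: RunConfig) -> Path:
    """Run the full comparison described by ``config``; returns the bundle
    directory. A replicate that fails is logged, marked failed in the
    manifest, and does not stop the run."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = _resolve_tree(config)
    names = node_names(tree)
    depths = phylo_io.node_depth(tree)

    if config.mode == "synthetic":
        n_reps = config.n_replicates
        truth_count: float | None = float(config.n_families)
    else:
        n_reps = len(config.matrices)
        truth_count = float(config.truth) if config.truth is not None else None

    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_nodes": tree.n_nodes,
        "n_tips": tree.n_tips,
        "replicates": [],
        "outputs": [],
    }
    long_rows: list[dict] = []

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(outdir)))

    tree_path = outdir / "tree.nwk"
    phylo_io.write_newick(tree, tree_path)
    record(tree_path)

    for rep in range(n_reps):
        repdir = outdir / f"rep{rep}"
        repdir.mkdir(exist_ok=True)
        rep_info: dict = {"replicate": rep, "status": "ok"}
        try:
            matrix, rep_info = _prepare_replicate(config, tree, rep, repdir,
                                                  rep_info, record)
            for method in config.methods:
                t0 = time.perf_counter()
                table = _run_method(method, config, tree, matrix, repdir,
                                    record)
                rep_info[f"{method}_seconds"] = round(
                    time.perf_counter() - t0, 3)
                df = table.to_frame(tree)
                df.insert(1, "name", names)
                path = repdir / f"{method}_nodes.tsv"
                df.to_csv(path, sep="\t", index=False)
                record(path)
                if truth_count is not None:
                    summ = counting.overestimation_summary(
                        table.counts, truth_count, depths)
                    spath = repdir / f"{method}_overestimation.tsv"
                    summ.per_node.to_csv(spath, sep="\t", index=False)
                    record(spath)
                for v in range(tree.n_nodes):
                    long_rows.append({
                        "replicate": rep, "method": method, "node": v,
                        "name": names[v], "depth": depths[v],
                        "is_tip": tree.is_tip(v),
                        "count": table.counts[v],
                        "gains": table.gains[v],
                        "losses": table.losses[v]})
            logger.info("replicate %d done: %s", rep,
                        {k: v for k, v in rep_info.items()
                         if k != "replicate"})
        except Exception:
            logger.exception("replicate %d failed", rep)
            rep_info["status"] = "failed"
        manifest["replicates"].append(rep_info)

    long_df = pd.DataFrame(long_rows)
    long_path = outdir / "counts_by_node.tsv"
    long_df.to_csv(long_path, sep="\t", index=False)
    record(long_path)
    manifest["versions"] = {"dolloml": _version(), "numpy": np.__version__}
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


def _version() -> str:
    from . import __version__
    return __version__


def _prepare_replicate(config, tree, rep, repdir, rep_info, record):
    if config.mode == "synthetic":
        rate = None
        if config.rate_scalars is not None:
            rate = float(config.rate_scalars[rep % len(config.rate_scalars)])
        sim = synthetic_data.SimulationConfig(
            tree=tree, seed=config.seed, n_families=config.n_families,
            seq_length=config.seq_length, rate_scalar=rate,
            alpha_sites=config.alpha_sites,
            identity_threshold=config.identity_threshold,
            paralog_fraction=config.paralog_fraction)
        table, truth = synthetic_data.generate_dataset(sim, replicate=rep)
        og_path, single_path = repdir / "orthogroups.tsv", \
            repdir / "singletons.tsv"
        phylo_io.write_orthogroups_tsv(table, og_path, single_path,
                                       species=tree.tip_labels)
        record(og_path), record(single_path)
        truth_path = repdir / "truth.json"
        truth.to_json(truth_path)
        record(truth_path)
        matrix = phylo_io.orthogroups_to_matrix(table, tree.tip_labels)
        rep_info.update(rate_scalar=truth.rate_scalar,
                        alpha_sites=truth.alpha_sites,
                        n_orthogroups=matrix.n_characters,
                        n_singletons=len(table.singletons))
    else:
        matrix = _load_matrix(config.matrices[rep])
        rep_info.update(source=str(config.matrices[rep]),
                        n_orthogroups=matrix.n_characters)
    mat_path = repdir / "matrix.tsv"
    phylo_io.write_matrix_tsv(matrix, mat_path)
    record(mat_path)
    return matrix, rep_info


def _run_method(method, config, tree, matrix, repdir, record):
    if method == "dollo":
        states = dollo.reconstruct_dollo(tree, matrix)
        if config.write_states:
            path = repdir / "dollo_states.tsv"
            pd.DataFrame(states.states,
                         columns=matrix.characters).to_csv(path, sep="\t")
            record(path)
        return counting.gains_losses_dollo(tree, states)
    # maximum likelihood
    free = tuple(p for p in config.ml_free
                 if not (config.fixed_branch_lengths
                         and p == "branch_lengths"))
    fit = ml_ancestral.fit_model(tree, matrix, free=free,
                                 n_categories=config.n_categories)
    post = ml_ancestral.marginal_posteriors(fit.tree, matrix, fit.model)
    params_path = repdir / "ml_params.json"
    with open(params_path, "w") as fh:
        json.dump({"kappa": fit.model.kappa, "alpha": fit.model.alpha,
                   "logL": fit.log_likelihood,
                   "n_sweeps": fit.n_sweeps}, fh, indent=1)
    record(params_path)
    if config.write_states:
        path = repdir / "ml_posteriors.tsv"
        pd.DataFrame(post.probs, columns=matrix.characters).to_csv(
            path, sep="\t")
        record(path)
    return counting.gains_losses_ml(fit.tree, post,
                                    mode=config.gain_loss_mode)


# ---------------------------------------------------------------------------
# Plotting (optional; requires matplotlib)
# ---------------------------------------------------------------------------

def plot_report(bundle: str | Path) -> list[Path]:
    """Render count line plots per method (one line per replicate, nodes on
    the x axis) and per-node count distributions ordered by proximity to
    the root. Purely presentational: every number comes from the bundle."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bundle = Path(bundle)
    counts_path = bundle / "counts_by_node.tsv"
    if not counts_path.exists():
        raise FileNotFoundError(f"no counts table at {counts_path}")
    df = pd.read_csv(counts_path, sep="\t")
    out: list[Path] = []
    if df.empty:
        logger.warning("empty replicate set; nothing to plot")
        return out
    internal = df[~df["is_tip"]]
    for method, sub in internal.groupby("method"):
        fig, ax = plt.subplots(figsize=(8, 4))
        for rep, reps in sub.groupby("replicate"):
            reps = reps.sort_values("node")
            ax.plot(reps["node"], reps["count"], alpha=0.7,
                    label=f"replicate {rep}")
        ax.set_xlabel("internal node (post-order id)")
        ax.set_ylabel("inferred gene count")
        ax.set_title(f"{method}: per-node counts")
        ax.legend(fontsize="small")
        path = bundle / f"{method}_counts.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        out.append(path)

        order = (sub.groupby("node")["depth"].first()
                 .sort_values(kind="stable").index)
        data = [sub[sub["node"] == v]["count"].to_numpy() for v in order]
        fig, ax = plt.subplots(figsize=(10, 4))
        ax.boxplot(data, tick_labels=[str(v) for v in order])
        ax.set_xlabel("internal node, root-proximal first")
        ax.set_ylabel("inferred gene count")
        ax.set_title(f"{method}: per-node count distributions")
        ax.tick_params(axis="x", labelsize=6, rotation=90)
        path = bundle / f"{method}_node_distributions.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        out.append(path)
    return out
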