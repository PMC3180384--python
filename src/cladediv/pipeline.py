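"""Orchestration: run the full diversification battery and write reports.

``run_battery`` ties the pieces together for one dataset: validate and
rescale the chronogram, compute gamma with its asymptotic p, run the MCCR
test, fit all diversification models, and compute ΔAIC with its
parametric-bootstrap p-value.  ``write_report`` emits a Table-1-style TSV
(one row per dataset/method) plus per-dataset LTT curves as CSV.

A small click CLI (``cladediv``) exposes the battery (`run`), single-model
simulation (`simulate`), the nine-clade synthetic fixture suite
(`fixtures`), and a standalone MCCR test (`mccr`).  Exit codes: 0 success,
2 validation error, 3 numerical error.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import divmodels, divstats, simulate, treeio
from .treeio import Chronogram, ChronogramError, TreeSample

__all__ = [
    "DatasetSpec",
    "BatteryConfig",
    "BatteryRecord",
    "run_battery",
    "write_report",
    "read_config",
    "main",
]

log = logging.getLogger("cladediv")


@dataclass
class DatasetSpec:
    """One clade to analyze: a tree file plus sampling metadata."""

    name: str
    tree_path: str
    n_sampled: int
    known_total: int
    age: float | None = None
    tree_kind: str = "single"  # or "sample"
    summary_tree_path: str | None = None
    method_label: str = ""


@dataclass
class BatteryConfig:
    mccr_reps: int = 5000
    daic_reps: int = 1000
    alpha: float = 0.05
    extra_fraction: float = 0.10
    seed: int = 0
    restarts: int = 10
    extended: bool = False
    gamma_sample_max: int = 1000


@dataclass
class BatteryRecord:
    """One Table-1-style row of results."""

    dataset: str
    method_label: str
    n_sampled: int
    known_total: int
    full_size: int
    age: float | None
    gamma: float
    gamma_p: float
    gamma_c: float
    mccr_p: float
    fits: dict[str, divmodels.ModelFit]
    best_rc: str
    best_rv: str
    delta_aic: float
    delta_aic_p: float
    ltt: divstats.LTTCurve
    gamma_sample: divstats.GammaSampleSummary | None = None
    flags: list[str] = field(default_factory=list)


def _load_tree(spec: DatasetSpec) -> tuple[Chronogram, TreeSample | None]:
    parsed = treeio.parse_newick(spec.tree_path)
    if spec.tree_kind == "single":
        if isinstance(parsed, TreeSample):
            raise ChronogramError(
                f"{spec.name}: expected a single tree, found {len(parsed)}"
            )
        return parsed, None
    sample = parsed if isinstance(parsed, TreeSample) else TreeSample([parsed])
    if spec.summary_tree_path is None:
        raise ChronogramError(
            f"{spec.name}: tree_kind=sample requires a summary tree file"
        )
    summary = treeio.parse_newick(spec.summary_tree_path)
    if isinstance(summary, TreeSample):
        raise ChronogramError(
            f"{spec.name}: summary tree file must contain one tree"
        )
    return summary, sample


def run_battery(spec: DatasetSpec, config: BatteryConfig | None = None) -> BatteryRecord:
    """Run gamma, MCCR, model fits, and ΔAIC selection for one dataset."""
    if config is None:
        config = BatteryConfig()
    try:
        tree, sample = _load_tree(spec)
    except ChronogramError as exc:
        raise ChronogramError(f"{spec.name}: {exc}") from exc
    if tree.n_tips != spec.n_sampled:
        raise ChronogramError(
            f"{spec.name}: tree has {tree.n_tips} tips but spec says "
            f"{spec.n_sampled}"
        )
    if spec.known_total < spec.n_sampled:
        raise ChronogramError(
            f"{spec.name}: known_total < n_sampled"
        )
    tree = treeio.scale_to_unit_depth(tree)
    bt = treeio.branching_times(tree)
    full = simulate.full_clade_size(spec.known_total, config.extra_fraction)
    log.info(
        "%s: n=%d known=%d full=%d seed=%d mccr_reps=%d daic_reps=%d",
        spec.name, spec.n_sampled, spec.known_total, full, config.seed,
        config.mccr_reps, config.daic_reps,
    )

    gres = divstats.gamma_statistic(bt)
    mccr = divstats.mccr_test(
        gres.gamma,
        spec.n_sampled,
        spec.known_total,
        reps=config.mccr_reps,
        alpha=config.alpha,
        extra_fraction=config.extra_fraction,
        seed=config.seed,
    )
    sel = divmodels.select_models(bt, restarts=config.restarts)
    fits = dict(sel.fits)
    if config.extended:
        fits.update(divmodels.fit_extended(bt, restarts=config.restarts))
    daic_p = divmodels.delta_aic_p(
        sel.delta_aic,
        spec.n_sampled,
        spec.known_total,
        reps=config.daic_reps,
        extra_fraction=config.extra_fraction,
        seed=config.seed + 1,
        restarts=config.restarts,
    )

    gamma_sample = None
    if sample is not None:
        trees = sample.trees
        if len(trees) > config.gamma_sample_max:
            rng = np.random.default_rng(config.seed)
            idx = rng.choice(
                len(trees), size=config.gamma_sample_max, replace=False
            )
            trees = [trees[i] for i in sorted(idx)]
        gamma_sample = divstats.gamma_over_sample(TreeSample(trees))

    flags = [
        f"{m}:non-converged" for m, f in fits.items() if not f.converged
    ]
    return BatteryRecord(
        dataset=spec.name,
        method_label=spec.method_label,
        n_sampled=spec.n_sampled,
        known_total=spec.known_total,
        full_size=full,
        age=spec.age,
        gamma=gres.gamma,
        gamma_p=gres.p_one_tailed,
        gamma_c=mccr.critical_value,
        mccr_p=mccr.p,
        fits=fits,
        best_rc=sel.best_rc.model,
        best_rv=sel.best_rv.model,
        delta_aic=sel.delta_aic,
        delta_aic_p=daic_p,
        ltt=divstats.ltt(bt),
        gamma_sample=gamma_sample,
        flags=flags,
    )


_REPORT_COLUMNS = [
    "dataset", "method", "n_sampled", "known_total", "full_size", "age_ma",
    "gamma", "gamma_p", "gamma_C", "mccr_p",
    "pb_LH", "pb_AIC", "pb_r1",
    "bd_LH", "bd_AIC", "bd_r", "bd_a",
    "best_rv", "rv_LH", "rv_AIC", "rv_r1", "rv_r2", "rv_K", "rv_x", "rv_st",
    "delta_aic", "delta_aic_p", "flags",
]


def _fmt(x, sig=False):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    if isinstance(x, str):
        return x
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{x:.3g}" if sig else f"{x:.3f}"


def write_report(records: list[BatteryRecord], path, ltt_dir=None) -> None:
    """Write a Table-1-style TSV plus companion per-dataset LTT CSVs.

    Numbers are printed to 3 decimals, p-values to 3 significant figures.
    """
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    rows = []
    for rec in records:
        pb = rec.fits["yule1"]
        bd = rec.fits["bd"]
        rv = rec.fits[rec.best_rv]
        row = {
            "dataset": rec.dataset,
            "method": rec.method_label or "NA",
            "n_sampled": rec.n_sampled,
            "known_total": rec.known_total,
            "full_size": rec.full_size,
            "age_ma": _fmt(rec.age),
            "gamma": _fmt(rec.gamma),
            "gamma_p": _fmt(rec.gamma_p, sig=True),
            "gamma_C": _fmt(rec.gamma_c),
            "mccr_p": _fmt(rec.mccr_p, sig=True),
            "pb_LH": _fmt(pb.loglik),
            "pb_AIC": _fmt(pb.aic),
            "pb_r1": _fmt(pb.params["r1"]),
            "bd_LH": _fmt(bd.loglik),
            "bd_AIC": _fmt(bd.aic),
            "bd_r": _fmt(bd.params["r"]),
            "bd_a": _fmt(bd.params["a"]),
            "best_rv": rec.best_rv,
            "rv_LH": _fmt(rv.loglik),
            "rv_AIC": _fmt(rv.aic),
            "rv_r1": _fmt(rv.params.get("r1")),
            "rv_r2": _fmt(rv.params.get("r2")),
            "rv_K": _fmt(rv.params.get("K")),
            "rv_x": _fmt(rv.params.get("x")),
            "rv_st": _fmt(rv.params.get("st")),
            "delta_aic": _fmt(rec.delta_aic),
            "delta_aic_p": _fmt(rec.delta_aic_p, sig=True),
            "flags": ";".join(rec.flags) or "ok",
        }
        rows.append(row)
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    ltt_dir = Path(ltt_dir) if ltt_dir is not None else path.parent
    for rec in records:
        rec.ltt.to_csv(ltt_dir / f"{rec.dataset}_ltt.csv")


# ---------------------------------------------------------------------------
# Config + CLI
# ---------------------------------------------------------------------------


def read_config(path) -> tuple[list[DatasetSpec], BatteryConfig]:
    """Parse a flat key-value config file.

    Scalar keys: ``seed``, ``mccr_reps``, ``daic_reps``, ``alpha``,
    ``extra_fraction``, ``restarts``, ``extended``.  Each ``dataset`` line
    declares one clade:

        dataset = name path n_sampled known_total [age]
    """
    cfg = BatteryConfig()
    specs: list[DatasetSpec] = []
    base = Path(path).parent
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "dataset":
            parts = value.split()
            if len(parts) not in (4, 5):
                raise ValueError(
                    f"{path}:{lineno}: dataset needs "
                    "'name path n_sampled known_total [age]'"
                )
            tree_path = parts[1]
            if not Path(tree_path).is_absolute():
                tree_path = str(base / tree_path)
            specs.append(
                DatasetSpec(
                    name=parts[0],
                    tree_path=tree_path,
                    n_sampled=int(parts[2]),
                    known_total=int(parts[3]),
                    age=float(parts[4]) if len(parts) == 5 else None,
                )
            )
        elif key in ("seed", "mccr_reps", "daic_reps", "restarts"):
            setattr(cfg, key, int(value))
        elif key in ("alpha", "extra_fraction"):
            setattr(cfg, key, float(value))
        elif key == "extended":
            cfg.extended = value.lower() in ("1", "true", "yes")
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return specs, cfg


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log progress to stderr.")
def main(verbose):
    """Diversification-dynamics battery for ultrametric chronograms."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _run_guarded(fn):
    try:
        fn()
    except (ChronogramError, ValueError) as exc:
        click.echo(f"validation error: {exc}", err=True)
        sys.exit(2)
    except (ArithmeticError, RuntimeError) as exc:
        click.echo(f"numerical error: {exc}", err=True)
        sys.exit(3)


@main.command("run")
@click.option("--config", "config_path", required=True,
              type=click.Path(exists=True))
@click.option("--out-dir", default=".", type=click.Path())
def run_cmd(config_path, out_dir):
    """Run the full battery over the datasets in a config file."""

    def go():
        specs, cfg = read_config(config_path)
        if not specs:
            raise ValueError("config declares no datasets")
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records = [run_battery(spec, cfg) for spec in specs]
        write_report(records, out / "battery_report.tsv")
        click.echo(str(out / "battery_report.tsv"))

    _run_guarded(go)


@main.command("simulate")
@click.option("--model", type=click.Choice(["yule", "bd", "yule2", "ddl", "ddx"]),
              default="yule")
@click.option("--n-tips", "n_tips", type=int, required=True)
@click.option("--lam", type=float, default=1.0)
@click.option("--mu", type=float, default=0.0)
@click.option("--r1", type=float, default=1.0)
@click.option("--r2", type=float, default=1.0)
@click.option("--big-k", "K", type=float, default=0.0)
@click.option("--x", type=float, default=0.0)
@click.option("--st", type=float, default=0.0)
@click.option("--seed", type=int, default=0)
@click.option("-o", "--out", type=click.Path(), default=None)
def simulate_cmd(model, n_tips, lam, mu, r1, r2, K, x, st, seed, out):
    """Simulate one reconstructed tree and print/write its Newick."""

    def go():
        cfg = simulate.SimConfig(
            model=model, n_tips=n_tips, lam=lam, mu=mu,
            r1=r1, r2=r2, K=K, x=x, st=st, seed=seed,
        )
        tree = simulate.simulate_tree(cfg)
        if out:
            treeio.write_newick(tree, out)
        else:
            click.echo(tree.as_newick(), nl=False)

    _run_guarded(go)


@main.command("fixtures")
@click.option("--out-dir", required=True, type=click.Path())
@click.option("--seed", type=int, default=0)
def fixtures_cmd(out_dir, seed):
    """Write the nine-clade synthetic fixture suite."""

    def go():
        paths = simulate.make_fixture_suite(out_dir, seed=seed)
        for p in paths:
            click.echo(str(p))

    _run_guarded(go)


@main.command("mccr")
@click.option("--tree", "tree_path", required=True,
              type=click.Path(exists=True))
@click.option("--known-total", type=int, required=True)
@click.option("--reps", type=int, default=5000)
@click.option("--alpha", type=float, default=0.05)
@click.option("--extra-fraction", type=float, default=0.10)
@click.option("--seed", type=int, default=0)
def mccr_cmd(tree_path, known_total, reps, alpha, extra_fraction, seed):
    """Standalone MCCR test for one chronogram."""

    def go():
        tree = treeio.parse_newick(tree_path)
        if isinstance(tree, TreeSample):
            raise ChronogramError("mccr expects a single tree")
        tree = treeio.scale_to_unit_depth(tree)
        g = divstats.gamma_statistic(treeio.branching_times(tree))
        res = divstats.mccr_test(
            g.gamma, tree.n_tips, known_total,
            reps=reps, alpha=alpha,
            extra_fraction=extra_fraction, seed=seed,
        )
        click.echo(
            f"gamma={g.gamma:.4f} gamma_C={res.critical_value:.4f} "
            f"p={res.p:.4g} (n_sampled={res.n_sampled}, "
            f"n_full={res.n_full}, reps={res.reps})"
        )

    _run_guarded(go)


if __name__ == "__main__":  # pragma: no cover
    main()
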