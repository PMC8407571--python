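"""Configuration, run manifests and the command-line workbench.

Experiments are described by a flat key/value text file with sections named
after the modules they configure (INI syntax); every default is resolved
and written back into a JSON run manifest next to the outputs, so a run is
fully reproducible from its manifest alone.  The ``dendronorm`` console
command exposes the experiment drivers: ``train`` (synthetic-image
feedforward comparison), ``recurrent-train`` (binary addition),
``sorn`` (self-organising network), ``cable`` (analytics on a parameter
grid), ``analyze`` (connectivity statistics of a fresh layer) and
``compare`` (mean ± sd across run manifests).
"""

from __future__ import annotations

import configparser
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__, cable, experiments, graph_analysis, sparse_net

__all__ = ["RunManifest", "load_config", "run_experiment", "compare_runs", "cli"]


_EXPERIMENTS = ("train", "recurrent-train", "sorn", "cable", "analyze")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config, seeds, versions, metrics."""

    experiment: str
    seed: int
    config: dict
    code_version: str = __version__
    python: str = field(default_factory=platform.python_version)
    metrics: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_config(path) -> dict:
    """Parse the flat key/value config file into nested dicts.

    Sections mirror module names; values are parsed as JSON scalars where
    possible (numbers, booleans) and kept as strings otherwise.  Unknown
    experiment names raise immediately with an explicit message.
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(path)
    out: dict = {}
    for section in parser.sections():
        out[section] = {}
        for key, raw in parser[section].items():
            try:
                out[section][key] = json.loads(raw)
            except json.JSONDecodeError:
                out[section][key] = raw
    exp = out.get("run", {}).get("experiment")
    if exp not in _EXPERIMENTS:
        raise ValueError(
            f"config must set [run] experiment to one of {_EXPERIMENTS}, got {exp!r}"
        )
    return out


def run_experiment(config_file, out_dir) -> RunManifest:
    """Execute the experiment a config file describes; write outputs + manifest."""
    config = load_config(config_file)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp = config["run"]["experiment"]
    seed = int(config["run"].get("seed", 0))
    manifest = RunManifest(experiment=exp, seed=seed, config=config)

    if exp == "train":
        kw = config.get("train", {})
        res = experiments.image_task_comparison(seed, **kw)
        rows = []
        for label in ("control", "normalised"):
            for epoch, cost in enumerate(res[label]["train_curve"]):
                rows.append(
                    {"variant": label, "epoch": epoch, "train_cost": cost, "seed": seed}
                )
            manifest.metrics[label] = {
                "test_cost": res[label]["test_cost"],
                "test_accuracy": res[label]["test_accuracy"],
            }
        pd.DataFrame(rows).to_csv(out / "learning_curves.csv", index=False)
    elif exp == "recurrent-train":
        kw = dict(config.get("recurrent", {}))
        res, _ = experiments.train_binary_addition(
            bool(kw.pop("normalised", True)), bool(kw.pop("sparse_input", False)),
            seed, **kw,
        )
        curve = res.pop("train_curve")
        manifest.metrics = res
        pd.DataFrame(
            {"epoch": np.arange(len(curve)), "train_cost": curve, "seed": seed}
        ).to_csv(out / "learning_curves.csv", index=False)
    elif exp == "sorn":
        kw = config.get("sorn", {})
        res = experiments.sorn_run(seed, **kw)
        manifest.calibration["theta_spike"] = res["theta"]
        manifest.metrics = {
            "score": res["score"],
            "weight_cv_before": res["before"]["weight_cv"],
            "weight_cv_after": res["after"]["weight_cv"],
            "voltage_cv_after": res["after"]["voltage_cv"],
            "mean_spike_rate": float(np.mean(res["spike_rates"])),
        }
        for tag in ("before", "after"):
            pd.DataFrame(
                {
                    "length": res[tag]["lengths"],
                    "afferent_count": res[tag]["counts"],
                }
            ).to_csv(out / f"distributions_{tag}.csv", index=False)
    elif exp == "cable":
        kw = dict(config.get("cable", {}))
        op = kw.pop("operation", "transfer_resistance")
        grid = _cable_grid(op, kw)
        grid.to_csv(out / "cable_grid.csv", index=False)
        manifest.metrics["rows"] = len(grid)
    elif exp == "analyze":
        kw = config.get("analyze", {})
        rng = np.random.default_rng(seed)
        layer = sparse_net.init_sparse(
            int(kw.get("fan_in", 784)), int(kw.get("m", 100)),
            float(kw.get("epsilon", 0.2)), rng,
        )
        stats = graph_analysis.degree_and_weight_stats(layer)
        manifest.metrics = {
            "mean_in_degree": float(layer.n.mean()),
            "connections": layer.n_connections(),
        }
        counts, edges = stats["in_degree"]
        pd.DataFrame({"bin_left": edges[:-1], "count": counts}).to_csv(
            out / "in_degree_histogram.csv", index=False
        )

    manifest.save(out / "manifest.json")
    return manifest


def _cable_grid(op: str, kw: dict) -> pd.DataFrame:
    lengths = np.asarray(kw.get("lengths", [250, 500, 1000, 2000]), dtype=float)
    xs = np.linspace(0.0, 1.0, int(kw.get("n_x", 5)))  # fractions of L
    kernel = cable.SynapticKernel()
    rows = []
    for l in lengths:
        p = cable.CableParameters(l=l, rho=float(kw.get("rho", 0.0)))
        for fx in xs:
            x = fx * p.L
            if op == "transfer_resistance":
                val = float(cable.transfer_resistance(p, x))
            elif op == "impulse_response":
                val = float(cable.impulse_response(p, x, float(kw.get("t_norm", 1.0))))
            elif op == "mean_synaptic_voltage":
                val = float(cable.mean_synaptic_voltage(p, kernel, float(kw.get("t", 0.01))))
            elif op == "total_voltage":
                val = cable.total_voltage(p, kernel)[0]
            else:
                raise ValueError(f"unknown cable operation {op!r}")
            rows.append({"l_um": l, "X": x, "output": val})
    return pd.DataFrame(rows)


def compare_runs(manifest_paths) -> pd.DataFrame:
    """Mean ± sd of every numeric metric across run manifests."""
    records = []
    for path in manifest_paths:
        data = json.loads(Path(path).read_text())
        flat = _flatten(data.get("metrics", {}))
        flat["seed"] = data.get("seed")
        records.append(flat)
    df = pd.DataFrame(records)
    numeric = df.select_dtypes("number").drop(columns=["seed"], errors="ignore")
    return pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std(ddof=0)})


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, (int, float)):
            out[key] = v
    return out


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Dendritic normalisation workbench."""


def _config_command(name: str):
    @cli.command(name)
    @click.argument("config_file", type=click.Path(exists=True))
    @click.option("--out", "out_dir", default="runs", show_default=True)
    def _cmd(config_file, out_dir):
        manifest = run_experiment(config_file, out_dir)
        click.echo(json.dumps(manifest.metrics, indent=2, default=_jsonify))

    return _cmd


for _name in _EXPERIMENTS:
    _config_command(_name)


@cli.command("compare")
@click.argument("manifests", nargs=-1, type=click.Path(exists=True))
def _compare(manifests):
    """Summarise metrics across run manifests (mean ± sd per metric)."""
    click.echo(compare_runs(manifests).to_string())
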