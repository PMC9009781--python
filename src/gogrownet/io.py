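"""Dataset container I/O, CSV export, run configuration, test fixtures.

Datasets are stored one file per experimental configuration in an HDF5
container with groups ``/data`` ([n_t, n_x, 2]), ``/grid``, ``/config``
and ``/provenance``.  Run configurations are YAML documents validated by a
strict pydantic schema (unknown keys rejected); the defaults reproduce the
benchmark setup exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .gogrow import GoGrowParams, make_benchmark
from .network import ExplanatoryNet, ParametricRamp
from .simulate import (
    DimensionlessParams,
    ExperimentConfig,
    GridSpec,
    SimulationDataset,
    build_grid,
    run_experiment_battery,
)

__all__ = [
    "SCHEMA_VERSION",
    "save_dataset",
    "load_dataset",
    "export_csv",
    "save_net",
    "load_net",
    "make_test_fixture",
    "RunConfig",
    "load_run_config",
]

SCHEMA_VERSION = 1


def save_dataset(dataset: SimulationDataset, path) -> None:
    """Write a dataset container (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("data", data=dataset.data)
        g = f.create_group("grid")
        for name in ("dxi", "dtau", "n_x", "n_t", "tau_star"):
            g.attrs[name] = getattr(dataset.grid, name)
        c = f.create_group("config")
        left, right = dataset.config.boundary_at(0.0)
        c.attrs["o2_left"] = left
        c.attrs["o2_right"] = right
        if dataset.config.label is not None:
            c.attrs["k"] = dataset.config.label
        if dataset.ground_truth is not None:
            c.attrs["family"] = dataset.ground_truth.family
            for pname in ("theta", "delta_theta", "k_half"):
                attr = "k" if pname == "k_half" else pname
                val = getattr(dataset.ground_truth.params, attr)
                if val is not None:
                    c.attrs[pname] = val
        p = f.create_group("provenance")
        for key, val in dataset.provenance.items():
            p.attrs[key] = val


def load_dataset(path) -> SimulationDataset:
    """Read a dataset container written by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {version!r}")
        for group in ("grid", "config"):
            if group not in f:
                raise ValueError(f"corrupted container: missing /{group}")
        data = f["data"][...]
        g = f["grid"].attrs
        grid = GridSpec(
            dxi=float(g["dxi"]), dtau=float(g["dtau"]), n_x=int(g["n_x"]),
            n_t=int(g["n_t"]), tau_star=float(g["tau_star"]),
        )
        c = f["config"].attrs
        config = ExperimentConfig(
            o2_left=float(c["o2_left"]), o2_right=float(c["o2_right"]),
            label=int(c["k"]) if "k" in c else None,
        )
        truth = None
        if "family" in c:
            kwargs = {}
            for pname, attr in (
                ("theta", "theta"), ("delta_theta", "delta_theta"), ("k_half", "k"),
            ):
                if pname in c:
                    kwargs[attr] = float(c[pname])
            truth = make_benchmark(str(c["family"]), GoGrowParams(**kwargs))
        provenance = dict(f["provenance"].attrs) if "provenance" in f else {}
    return SimulationDataset(
        data=data, grid=grid, config=config, ground_truth=truth,
        provenance=provenance,
    )


def export_csv(dataset: SimulationDataset, path) -> int:
    """Long-format export (tau, xi, cell, oxygen); returns the row count."""
    if dataset.data.size == 0:
        raise ValueError("empty dataset")
    n_t, n_x, _ = dataset.data.shape
    taus = np.repeat(dataset.grid.taus, n_x)
    xis = np.tile(dataset.grid.xi, n_t)
    df = pd.DataFrame(
        {
            "tau": taus,
            "xi": xis,
            "cell": dataset.data[:, :, 0].ravel(),
            "oxygen": dataset.data[:, :, 1].ravel(),
        }
    )
    df.to_csv(path, index=False)
    return len(df)


def save_net(model, path) -> None:
    """Serialize a trained switch model (network or parametric ramp)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if isinstance(model, ParametricRamp):
            f.attrs["kind"] = "parametric_ramp"
            f.attrs["theta"] = model.theta
        else:
            f.attrs["kind"] = "explanatory_net"
            f.attrs["widths"] = np.asarray(model.widths)
            f.attrs["seed"] = model.seed
            f.create_dataset("params", data=model.get_flat())


def load_net(path):
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        if kind == "parametric_ramp":
            return ParametricRamp(theta=float(f.attrs["theta"]))
        net = ExplanatoryNet(
            widths=tuple(int(w) for w in f.attrs["widths"]),
            seed=int(f.attrs["seed"]),
        )
        net.set_flat(f["params"][...])
        return net


def make_test_fixture(seed: int = 0) -> list[SimulationDataset]:
    """Small deterministic battery for fast tests.

    Three oxygenation configurations on a coarse chamber (l=10, dxi=1,
    tau*=0.5, dtau=0.01) with a Michaelis-Menten ground truth; generates
    in well under two seconds.
    """
    grid = build_grid(l=10.0, dxi=1.0, tau_star=0.5, dtau=0.01)
    truth = make_benchmark("michaelis_menten", k=2.0)
    params = DimensionlessParams(l=10.0)
    datasets = []
    for i, (left, right) in enumerate(((0.0, 0.0), (0.0, 4.0), (4.0, 4.0)), start=1):
        config = ExperimentConfig(o2_left=left, o2_right=right, label=i)
        from .simulate import generate_reference_dataset

        ds = generate_reference_dataset(config, params, truth, grid)
        ds.provenance["seed"] = seed
        datasets.append(ds)
    return datasets


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_Strict):
    l: float = 50.0
    dxi: float = 1.0
    tau_star: float = 10.0
    dtau: float = 0.01

    def build(self) -> GridSpec:
        return build_grid(self.l, self.dxi, self.tau_star, self.dtau)


class ParamsSection(_Strict):
    D1: float = 1.0
    chi: float = 1.0
    alpha1: float = 0.5
    cs: float = 10.0
    D2: float = 1.0
    alpha2: float = 0.05
    km: float = 2.0
    l: float = 50.0

    def build(self) -> DimensionlessParams:
        return DimensionlessParams(**self.model_dump())


class TruthSection(_Strict):
    family: str = "michaelis_menten"
    theta: Optional[float] = None
    delta_theta: Optional[float] = None
    k: Optional[float] = None
    printed_orientation: bool = False

    def build(self):
        kwargs = {
            name: getattr(self, name)
            for name in ("theta", "delta_theta", "k")
            if getattr(self, name) is not None
        }
        return make_benchmark(
            self.family, printed_orientation=self.printed_orientation, **kwargs
        )


class TrainingSection(_Strict):
    epochs: int = 1000
    learning_rate: float = 0.001
    adam_beta1: float = 0.8
    adam_beta2: float = 0.8
    train_fraction: float = 0.8
    seed: int = 0
    loss_reduction: str = "sum"
    hidden_widths: tuple[int, ...] = (1, 8, 8, 1)


class RunConfig(_Strict):
    """Validated, schema-checked run configuration (YAML-compatible)."""

    grid: GridSection = Field(default_factory=GridSection)
    params: ParamsSection = Field(default_factory=ParamsSection)
    truth: TruthSection = Field(default_factory=TruthSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    battery_rows: Optional[list[int]] = None
    seed: int = 0
    output_dir: str = "runs"


def load_run_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)


def simulate_battery_from_config(cfg: RunConfig) -> list[SimulationDataset]:
    grid = cfg.grid.build()
    params = cfg.params.build()
    truth = cfg.truth.build()
    datasets = run_experiment_battery(params, truth, grid, rows=cfg.battery_rows)
    for ds in datasets:
        ds.provenance["seed"] = cfg.seed
    return datasets


def write_battery(cfg: RunConfig, out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for ds in simulate_battery_from_config(cfg):
        p = out / f"config_{ds.config.label:02d}.h5"
        save_dataset(ds, p)
        paths.append(p)
    return paths
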