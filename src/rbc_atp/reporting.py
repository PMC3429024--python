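"""Figure/table reproduction and scenario reports.

Each reproduction emits the underlying numbers as CSV/JSON next to the plot,
and every run writes a manifest (configuration, seed, library versions) so
outputs can be regenerated exactly.  Plots are conveniences; the CSV/JSON
numbers are the testable surface.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .network.dilation import dilation_signal
from .network.geometry import CapillaryNetwork, read_network
from .network.oxygen import compute_saturation, prescribed_linear_saturation
from .network.scenarios import insulin_network_scenario
from .network.transport import TransportParameters, mean_capillary_atp, solve_atp_steady
from .pathway.calibrate import calibrate_release, dose_response
from .pathway.parameters import PathwayParameters, StimulusProtocol
from .pathway.scenarios import find_pde3_recovery, gi_deficit_scenario, insulin_scenario
from .pathway.simulate import simulate_pathway
from .synthetic import default_network_fixture

__all__ = ["RunConfig", "reproduce_figure", "run_scenarios", "write_manifest"]

FIGURE_TAGS = ("fig3", "fig4", "fig5", "fig6")


@dataclass
class RunConfig:
    """Options shared by the reproduction and scenario entry points."""

    out_dir: Path = Path("rbc_atp_out")
    params: PathwayParameters | None = None
    network_path: Path | None = None  # default: the seeded synthetic fixture
    seed: int = 42
    dz_um: float = 2.0
    steady_tol: float = 1e-6
    pulse_s: float = 0.040
    gp_fraction: float = 0.6
    insulin_pde3_rel: float = 1.87
    c0_scale: float = 0.5
    atp_in_uM: tuple[float, ...] = (0.0, 0.25)
    saturation: str = "computed"  # or "linear"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.params is None:
            self.params = PathwayParameters()
        if self.steady_tol <= 0 or self.dz_um <= 0 or self.pulse_s <= 0:
            raise ValueError("tolerances, dz and pulse duration must be > 0")
        if self.network_path is not None and not Path(self.network_path).exists():
            raise FileNotFoundError(f"network file {self.network_path} not found")

    def load_network(self) -> CapillaryNetwork:
        if self.network_path is not None:
            return read_network(self.network_path)
        return default_network_fixture(seed=self.seed)

    def build_saturation(self, network: CapillaryNetwork):
        if self.saturation == "linear":
            return prescribed_linear_saturation(network, 0.63, 0.17, dz_um=self.dz_um)
        return compute_saturation(network, dz_um=self.dz_um)


def write_manifest(out_dir: Path, config: dict, seed: int | None = None) -> Path:
    import numpy
    import scipy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in config.items()},
        "seed": seed,
        "versions": {
            "rbc_atp": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str) + "\n")
    return path


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["params"] = config.params.to_dict()
    return d


def reproduce_figure(tag: str, config: RunConfig) -> list[Path]:
    """Recompute one of the reference figure datasets; returns the files written.

    ``fig3``: pulse dynamics; ``fig4``: dose-response with and without
    insulin; ``fig5``: PDE3-activity scan; ``fig6``: network sO2/[ATP] fields.
    """
    if tag not in FIGURE_TAGS:
        raise ValueError(f"unknown figure tag {tag!r}; expected one of {FIGURE_TAGS}")
    out = config.out_dir / tag
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(out, {"figure": tag, **_config_dict(config)}, config.seed)
    return {
        "fig3": _fig3,
        "fig4": _fig4,
        "fig5": _fig5,
        "fig6": _fig6,
    }[tag](config, out)


def _fig3(config: RunConfig, out: Path) -> list[Path]:
    """Dynamic response to a 40 ms desaturation step to 15.7% sO2."""
    traj = simulate_pathway(
        config.params, StimulusProtocol.pulse(0.157, config.pulse_s)
    )
    csv_path = out / "trajectory.csv"
    traj.to_frame().to_csv(csv_path, index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in ("GPa", "cAMP", "PKAa", "CFTRa", "F_ATP"):
        frame = traj.to_frame()
        ax.plot(frame["time_s"] * 1e3, frame[col], label=col)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("activation / flux (model units)")
    ax.set_xlim(0, 1000)
    ax.legend(frameon=False)
    ax.set_title("Pathway response, 40 ms step to 15.7% sO2")
    png = out / "trajectory.png"
    fig.savefig(png, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return [csv_path, png]


def _fig4(config: RunConfig, out: Path) -> list[Path]:
    """Dose-response: total calibrated release vs sO2, control and insulin."""
    grid = np.round(np.arange(0.10, 1.0, 0.05), 3)
    calib = calibrate_release(config.params, pulse_duration=config.pulse_s)
    control = dose_response(
        config.params, grid, pulse_duration=config.pulse_s, calibration=calib
    )
    insulin = dose_response(
        config.params.replace(pde3_rel=config.insulin_pde3_rel),
        grid,
        pulse_duration=config.pulse_s,
        calibration=calib,
    )
    df = pd.DataFrame(
        {
            "sO2": grid,
            "release_control": control["release"],
            "release_insulin": insulin["release"],
        }
    )
    csv_path = out / "dose_response.csv"
    df.to_csv(csv_path, index=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(df["sO2"] * 100, df["release_control"], "o-", label="PDE3_rel = 1")
    ax.plot(
        df["sO2"] * 100,
        df["release_insulin"],
        "s-",
        label=f"PDE3_rel = {config.insulin_pde3_rel} (insulin)",
    )
    ax.set_xlabel("hemoglobin saturation (%)")
    ax.set_ylabel("total ATP release (nmol / 4e8 RBC)")
    ax.legend(frameon=False)
    png = out / "dose_response.png"
    fig.savefig(png, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return [csv_path, png]


def _fig5(config: RunConfig, out: Path) -> list[Path]:
    """ATP release and cAMP production at 15.7% sO2 vs PDE3 activity."""
    table = insulin_scenario(config.params, (1.0, 1.8, 4.1), pulse_duration=config.pulse_s)
    csv_path = out / "pde3_scan.csv"
    table.to_csv(csv_path, index=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(len(table))
    ax.bar(x - 0.2, table["release"], 0.4, label="ATP release", color="c")
    ax2 = ax.twinx()
    ax2.bar(x + 0.2, table["camp_integral"], 0.4, label="cAMP production", color="m")
    ax.set_xticks(x, [f"{v:g}" for v in table["pde3_rel"]])
    ax.set_xlabel("relative PDE3 activity")
    ax.set_ylabel("ATP release (nmol / 4e8 RBC)")
    ax2.set_ylabel("integrated cAMP (model units * s)")
    png = out / "pde3_scan.png"
    fig.savefig(png, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return [csv_path, png]


def _fig6(config: RunConfig, out: Path) -> list[Path]:
    """Steady sO2 and [ATP] along the network, normal vs impaired release."""
    network = config.load_network()
    sat = config.build_saturation(network)
    cases = {}
    for atp_in in config.atp_in_uM:
        for label, scale in (("normal", 1.0), ("impaired", config.c0_scale)):
            p = TransportParameters(atp_in=atp_in, release_scale=scale)
            cases[f"ATP_uM_{label}_in{atp_in:g}"] = solve_atp_steady(
                network, sat, p, steady_tol=config.steady_tol
            )
    frame = next(iter(cases.values())).to_frame(saturation=sat)
    for name, fld in cases.items():
        frame[name] = fld.values_uM
    frame = frame.drop(columns=["ATP_uM"])
    csv_path = out / "fields.csv"
    frame.to_csv(csv_path, index=False)

    summary = {
        "network_segments": len(network.segments),
        "sO2_range": [float(sat.values.min()), float(sat.values.max())],
    }
    for name, fld in cases.items():
        summary[name] = {
            "mean_uM": mean_capillary_atp(fld),
            "sigma_dilation": dilation_signal(fld, network).sigma,
        }
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(summary, indent=1) + "\n")

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(frame["z_um"], frame["S"] * 100, ".", ms=2)
    ax1.set_xlabel("z (um)")
    ax1.set_ylabel("sO2 (%)")
    for name in cases:
        ax2.plot(frame["z_um"], frame[name], ".", ms=2, label=name)
    ax2.set_xlabel("z (um)")
    ax2.set_ylabel("[ATP] (uM)")
    ax2.legend(frameon=False, fontsize=7)
    png = out / "fields.png"
    fig.savefig(png, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return [csv_path, json_path, png]


def run_scenarios(config: RunConfig) -> dict:
    """All headline perturbation predictions in one deterministic JSON report.

    Pathway: percent release decrease for a 40% Gi deficit and the PDE3
    activity that rescues it.  Network: mean [ATP] and sigma_dilation changes
    when release is halved, for each inlet concentration.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    write_manifest(config.out_dir, _config_dict(config), config.seed)
    params = config.params
    report: dict = {
        "gi_deficit_pct": gi_deficit_scenario(
            params, config.gp_fraction, pulse_duration=config.pulse_s
        ),
        "pde3_recovery": find_pde3_recovery(
            params, config.gp_fraction, pulse_duration=config.pulse_s
        ),
    }
    network = config.load_network()
    sat = config.build_saturation(network)
    report["network"] = insulin_network_scenario(
        network,
        sat,
        atp_in_values=config.atp_in_uM,
        impaired_scale=config.c0_scale,
        steady_tol=config.steady_tol,
    )
    (config.out_dir / "scenarios.json").write_text(
        json.dumps(report, indent=1) + "\n"
    )
    return report
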