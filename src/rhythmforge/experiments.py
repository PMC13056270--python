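"""The three computational experiments as seeded 2-D parameter sweeps.

Experiment 1 forces each model with Poisson (random) event trains over a grid
of input-frequency ratios × a model-specific parameter (neuron firing rate or
cricket relaxation rate), probing the models' intrinsic bias toward order.
Experiment 2 repeats the sweep with isochronous input, mapping the mode-locked
regions (Arnold-tongue structure) in which rhythmic categories appear.
Experiment 3 fixes the input frequency at the neuron's intrinsic rate and
sweeps the two connection-strength parameters (weight × synaptic rise time).

Every cell simulates a sequence with at least 100 output intervals, computes
the rhythm-ratio metrics, and records a per-cell seed derived deterministically
from the sweep seed and the grid indices, so sweeps are reproducible cell by
cell. Failed cells (e.g. a silent neuron) are annotated, not fatal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cricket import CricketParams, simulate_cricket
from .errors import InvalidParameterError, RhythmforgeError
from .generators import (
    EventSequence,
    generate_isochronous,
    generate_poisson,
    input_rate_for_ratio,
)
from .lif import LIFParams, current_for_rate, simulate_lif
from .metrics import (
    DEFAULT_TARGETS,
    TARGET_LABELS,
    build_bins,
    differential_entropy,
    intervals,
    on_integer_fraction,
    rhythm_ratios,
)

RATIO_GRID_DEFAULT = (1.0 / 6.0, 5.0 / 6.0)  # "1:5 to 5:1" in frequency-ratio units


@dataclass
class SweepConfig:
    """Configuration of one 2-D sweep.

    ``x_name``/``y_name`` define the axes: experiments 1-2 sweep
    ``frequency_ratio`` × (``firing_rate`` Hz for the neuron, or
    ``relaxation_rate`` for the cricket); experiment 3 sweeps connection
    ``weight`` (pA) × ``tau_syn`` (ms) at matched frequencies.
    """

    model: str = "neuron"                 # "neuron" | "cricket"
    input_kind: str = "poisson"           # "poisson" | "isochronous"
    x_name: str = "frequency_ratio"
    x_grid: np.ndarray = field(default_factory=lambda: np.linspace(*RATIO_GRID_DEFAULT, 21))
    y_name: str = "firing_rate"
    y_grid: np.ndarray = field(default_factory=lambda: np.linspace(10.0, 100.0, 21))
    n_intervals: int = 150                # analyzed output intervals per cell (>= 100)
    discard: int = 0                      # leading transient intervals dropped before analysis
    seed: int = 0
    neuron: LIFParams = field(default_factory=LIFParams)
    cricket: CricketParams = field(default_factory=CricketParams)
    intrinsic_rate: float = 40.0          # model rate (Hz) when the y-axis is not a rate
    phase_offset: float = 0.5             # isochronous input start, fraction of input period
    compute_input_entropy: bool = False
    store_ratios: bool = True

    def __post_init__(self) -> None:
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        self.y_grid = np.asarray(self.y_grid, dtype=float)
        if self.model not in ("neuron", "cricket"):
            raise InvalidParameterError(f"unknown model {self.model!r}")
        if self.input_kind not in ("poisson", "isochronous"):
            raise InvalidParameterError(f"unknown input kind {self.input_kind!r}")
        for grid, name in ((self.x_grid, "x_grid"), (self.y_grid, "y_grid")):
            if grid.size == 0:
                raise InvalidParameterError(f"{name} must be non-empty")
            if grid.size > 1 and np.any(np.diff(grid) <= 0):
                raise InvalidParameterError(f"{name} must be sorted and distinct")
        if self.n_intervals < 100:
            raise InvalidParameterError("n_intervals must be >= 100 per cell")
        if self.discard < 0:
            raise InvalidParameterError("discard must be non-negative")


@dataclass
class SweepResult:
    """Metric grids over the sweep plane (rows = y axis, columns = x axis)."""

    config: SweepConfig
    x_name: str
    x_values: np.ndarray
    y_name: str
    y_values: np.ndarray
    entropy: np.ndarray                       # (ny, nx), -inf allowed
    fractions: dict[str, np.ndarray]          # label "1:1" etc. -> (ny, nx)
    status: np.ndarray                        # (ny, nx) of str, "ok" or "failed: ..."
    seeds: np.ndarray                         # (ny, nx) per-cell seeds
    input_entropy: np.ndarray | None = None   # (ny, nx), experiment 1 only
    ratios: dict[tuple[int, int], np.ndarray] | None = None  # (iy, ix) -> ratio sample

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format: one row per cell per metric."""
        rows = []
        metric_grids: list[tuple[str, np.ndarray]] = [("entropy", self.entropy)]
        metric_grids += [(f"frac_{lbl.replace(':', '_')}", g) for lbl, g in self.fractions.items()]
        if self.input_entropy is not None:
            metric_grids.append(("input_entropy", self.input_entropy))
        for iy, y in enumerate(self.y_values):
            for ix, x in enumerate(self.x_values):
                for name, grid in metric_grids:
                    rows.append(
                        {
                            "x_value": x,
                            "y_value": y,
                            "metric": name,
                            "value": grid[iy, ix],
                            "status": self.status[iy, ix],
                            "seed": int(self.seeds[iy, ix]),
                        }
                    )
        return pd.DataFrame(rows)


def cell_seed(seed: int, ix: int, iy: int) -> int:
    """Deterministic per-cell seed below 2**31, derived from (seed, grid indices)."""
    return int(np.random.SeedSequence([seed, iy, ix]).generate_state(1)[0] % (2**31))


def _poisson_input(f_input: float, f_model: float, n_out: int, seed: int, slack: float) -> EventSequence:
    # enough events to cover the expected simulation window, and >= 101 events
    # so the input's own rhythm ratios are a valid >= 100-interval sample
    n_in = max(int(math.ceil(slack * (n_out + 2) * f_input / f_model)) + 20, 101 - 1, n_out)
    return generate_poisson(f_input, n_in, seed)


def _isochronous_input(f_input: float, f_model: float, n_out: int, phase_offset: float, slack: float) -> EventSequence:
    n_in = max(int(math.ceil(slack * (n_out + 2) * f_input / f_model)) + 20, 2)
    start = phase_offset * 1000.0 / f_input
    return generate_isochronous(f_input, n_in + 1, start=start)


def _run_cell(cfg: SweepConfig, x: float, y: float, seed: int) -> tuple[np.ndarray, EventSequence]:
    """Simulate one grid cell; returns (analyzed ratio sample, input sequence)."""
    n_total = cfg.n_intervals + cfg.discard
    if cfg.model == "neuron":
        base = cfg.neuron
        if cfg.x_name == "weight":  # experiment 3 axes
            f_model = cfg.intrinsic_rate
            params = replace(base, w=x, tau_syn=y, I_e=current_for_rate(f_model, base))
        else:
            f_model = y if cfg.y_name == "firing_rate" else cfg.intrinsic_rate
            params = replace(base, I_e=current_for_rate(f_model, base))
        slack = 1.3
    else:
        f_model = 1000.0 / cfg.cricket.T0
        rho = y if cfg.y_name == "relaxation_rate" else cfg.cricket.rho
        params = replace(cfg.cricket, rho=rho, seed=seed)
        slack = 2.0  # cricket periods can stretch up to (1 + max PRC) * T0

    ratio = 0.5 if cfg.x_name == "weight" else x
    f_input = input_rate_for_ratio(ratio, f_model)
    if cfg.input_kind == "poisson":
        inp = _poisson_input(f_input, f_model, n_total, seed, slack)
    else:
        inp = _isochronous_input(f_input, f_model, n_total, cfg.phase_offset, slack)

    if cfg.model == "neuron":
        out = simulate_lif(params, inp, n_total)
    else:
        out = simulate_cricket(params, inp, n_total + 1)
    times = out.times[cfg.discard:]
    return rhythm_ratios(intervals(times)), inp


def _run_sweep(cfg: SweepConfig) -> SweepResult:
    nx, ny = cfg.x_grid.size, cfg.y_grid.size
    bins = build_bins()
    entropy = np.full((ny, nx), np.nan)
    input_entropy = np.full((ny, nx), np.nan) if cfg.compute_input_entropy else None
    fractions = {TARGET_LABELS[t]: np.full((ny, nx), np.nan) for t in DEFAULT_TARGETS}
    status = np.full((ny, nx), "ok", dtype=object)
    seeds = np.zeros((ny, nx), dtype=np.int64)
    ratios_store: dict[tuple[int, int], np.ndarray] = {}

    for iy, y in enumerate(cfg.y_grid):
        for ix, x in enumerate(cfg.x_grid):
            seed = cell_seed(cfg.seed, ix, iy)
            seeds[iy, ix] = seed
            try:
                r, inp = _run_cell(cfg, float(x), float(y), seed)
            except RhythmforgeError as exc:
                status[iy, ix] = f"failed: {exc}"
                continue
            entropy[iy, ix] = differential_entropy(r)
            for t in DEFAULT_TARGETS:
                fractions[TARGET_LABELS[t]][iy, ix] = on_integer_fraction(r, t, bins)
            if input_entropy is not None:
                input_entropy[iy, ix] = differential_entropy(rhythm_ratios(intervals(inp)))
            if cfg.store_ratios:
                ratios_store[(iy, ix)] = r

    return SweepResult(
        config=cfg,
        x_name=cfg.x_name,
        x_values=cfg.x_grid.copy(),
        y_name=cfg.y_name,
        y_values=cfg.y_grid.copy(),
        entropy=entropy,
        fractions=fractions,
        status=status,
        seeds=seeds,
        input_entropy=input_entropy,
        ratios=ratios_store if cfg.store_ratios else None,
    )


def run_experiment1(cfg: SweepConfig) -> SweepResult:
    """Random (Poisson) input over frequency ratio × model parameter.

    Also computes each cell's input-sequence entropy so the output's entropy
    reduction can be read off directly.
    """
    if cfg.input_kind != "poisson":
        raise InvalidParameterError("experiment 1 requires poisson input")
    if cfg.x_name != "frequency_ratio":
        raise InvalidParameterError("experiment 1 sweeps frequency_ratio on the x-axis")
    cfg = replace_config(cfg, compute_input_entropy=True)
    return _run_sweep(cfg)


def run_experiment2(cfg: SweepConfig) -> SweepResult:
    """Isochronous input over frequency ratio × model parameter (mode locking)."""
    if cfg.input_kind != "isochronous":
        raise InvalidParameterError("experiment 2 requires isochronous input")
    if cfg.x_name != "frequency_ratio":
        raise InvalidParameterError("experiment 2 sweeps frequency_ratio on the x-axis")
    return _run_sweep(cfg)


def run_experiment3(cfg: SweepConfig) -> SweepResult:
    """Isochronous input at the neuron's intrinsic rate; weight × tau_syn sweep."""
    if cfg.model != "neuron":
        raise InvalidParameterError("experiment 3 applies to the neuron model only")
    if cfg.input_kind != "isochronous":
        raise InvalidParameterError("experiment 3 requires isochronous input")
    if cfg.x_name != "weight" or cfg.y_name != "tau_syn":
        raise InvalidParameterError("experiment 3 sweeps weight (x) by tau_syn (y)")
    return _run_sweep(cfg)


def replace_config(cfg: SweepConfig, **kwargs) -> SweepConfig:
    """Dataclass ``replace`` that re-runs validation."""
    return replace(cfg, **kwargs)


def experiment3_config(seed: int = 0, nx: int = 21, ny: int = 7, **kwargs) -> SweepConfig:
    """Default experiment-3 grid: weight 500-10,000 pA × tau_syn 2-8 ms."""
    return SweepConfig(
        model="neuron",
        input_kind="isochronous",
        x_name="weight",
        x_grid=np.linspace(500.0, 10_000.0, nx),
        y_name="tau_syn",
        y_grid=np.linspace(2.0, 8.0, ny),
        seed=seed,
        **kwargs,
    )


def render_outputs(result: SweepResult, out_dir: str | Path) -> list[Path]:
    """Write the sweep as a tidy CSV plus heatmap and density-slice figures.

    Heatmaps clip -inf entropy cells to the minimum finite value (shown in the
    same darkest hue); re-rendering the same result is byte-identical for the
    CSV. Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out_dir / "results.csv"
    result.to_dataframe().to_csv(csv_path, index=False, float_format="%.10g")
    written.append(csv_path)

    ent = result.entropy.copy()
    finite = ent[np.isfinite(ent)]
    if finite.size:
        ent[np.isneginf(ent)] = finite.min()
    fig, ax = plt.subplots(figsize=(6, 4.5))
    mesh = ax.pcolormesh(result.x_values, result.y_values, ent, shading="nearest", cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="differential entropy (nats)")
    ax.set_xlabel(result.x_name)
    ax.set_ylabel(result.y_name)
    ax.set_title("Differential entropy of output rhythm ratios")
    ent_path = out_dir / "entropy_heatmap.png"
    fig.savefig(ent_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(ent_path)

    fig, axes = plt.subplots(2, 4, figsize=(16, 7), constrained_layout=True)
    for ax, (label, grid) in zip(axes.flat, result.fractions.items()):
        mesh = ax.pcolormesh(
            result.x_values, result.y_values, grid, shading="nearest",
            cmap="Greens", vmin=0.0, vmax=1.0,
        )
        ax.set_title(f"on-integer fraction {label}")
        ax.set_xlabel(result.x_name)
        ax.set_ylabel(result.y_name)
    axes.flat[-1].axis("off")
    fig.colorbar(mesh, ax=axes.flat[-1], location="left", label="fraction")
    frac_path = out_dir / "fraction_heatmaps.png"
    fig.savefig(frac_path, dpi=150)
    plt.close(fig)
    written.append(frac_path)

    if result.ratios:
        from .metrics import kde_density
        from .errors import DegenerateDistributionError

        iy = result.y_values.size // 2
        grid = np.linspace(0.0, 1.0, 512)
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for ix in range(0, result.x_values.size, max(1, result.x_values.size // 6)):
            sample = result.ratios.get((iy, ix))
            if sample is None:
                continue
            try:
                dens = kde_density(sample, grid)
            except DegenerateDistributionError:
                continue
            ax.plot(grid, dens, label=f"{result.x_name}={result.x_values[ix]:.3g}")
        ax.axvline(0.5, color="red", linestyle=":", label="1:1 (isochrony)")
        ax.set_xlabel("rhythm ratio")
        ax.set_ylabel("density")
        ax.set_title(f"Rhythm-ratio densities at {result.y_name}={result.y_values[iy]:.3g}")
        ax.legend(fontsize=8)
        dens_path = out_dir / "density_slice.png"
        fig.savefig(dens_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(dens_path)

    return written
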