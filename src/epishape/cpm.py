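"""Cellular Potts Model simulation of a confluent monolayer.

Metropolis Monte Carlo on square or hexagonal periodic lattices under the
area/perimeter energy

    H = sum_i [ lambda_A (A_i - A0)^2 + lambda_P (P_i - P0)^2 ],

with the perimeter P_i counted as mismatched neighbor bonds (4-neighborhood
on the square lattice, 6 on the hexagonal).  kB = 1; the temperature is the
effective temperature of the monolayer, subsuming thermal and active
fluctuations.  Time is measured in Monte Carlo sweeps (one sweep =
lattice-size attempted copy moves).

A run initializes by Voronoi tessellation of random seed points, equilibrates
until the energy plateaus, then samples per-cell area, perimeter, gyration
eigenvalues and aspect ratio at fixed intervals, along with unwrapped
centroid trajectories for relaxation-time analysis via the self-overlap
function.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _cpm_kernel as kern
from .morphometry import PIXEL_MOMENT, ShapeEnsemble

__all__ = [
    "CPMConfig",
    "CPMState",
    "SimulationResult",
    "RelaxationResult",
    "energy",
    "metropolis_sweep",
    "run_simulation",
    "single_cell_mode",
    "relaxation_time",
    "voronoi_labels",
]

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass
class CPMConfig:
    """Simulation parameters; defaults follow a small fluid-regime monolayer."""

    lattice: str = "square"
    size: tuple[int, int] = (64, 40)
    n_cells: int = 64
    lambda_A: float = 1.0
    lambda_P: float = 0.5
    A0: float = 40.0
    P0: float = 26.0
    temperature: float = 12.5
    seed: int = 0
    equilibration_sweeps: int = 1500
    production_sweeps: int = 1500
    sampling_interval: int = 10
    check_connectivity: bool = True
    plateau_tol: float = 1e-2

    def __post_init__(self):
        self.size = (int(self.size[0]), int(self.size[1]))
        if self.lattice not in ("square", "hexagonal"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        rows, cols = self.size
        if rows < 4 or cols < 4:
            raise ValueError("lattice must be at least 4x4")
        for name in ("lambda_A", "lambda_P", "A0", "P0", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_cells * self.A0 > rows * cols:
            raise ValueError(
                f"infeasible config: n_cells*A0 = {self.n_cells * self.A0} exceeds "
                f"lattice size {rows * cols}"
            )
        if self.sampling_interval < 1 or self.production_sweeps < self.sampling_interval:
            raise ValueError("production schedule must allow at least one sample")

    @property
    def neighbors(self) -> np.ndarray:
        return kern.SQUARE_NEIGHBORS if self.lattice == "square" else kern.HEX_NEIGHBORS

    @property
    def ring(self) -> np.ndarray:
        return kern.SQUARE_RING if self.lattice == "square" else kern.HEX_RING

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size"] = list(self.size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CPMConfig":
        d = dict(d)
        if "size" in d:
            d["size"] = tuple(d["size"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "CPMConfig":
        """Load from YAML or JSON."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)


class CPMState:
    """Lattice configuration with per-cell area/perimeter caches."""

    def __init__(self, spins: np.ndarray, config: CPMConfig):
        spins = np.ascontiguousarray(spins, dtype=np.int64)
        if spins.shape != config.size:
            raise ValueError("spin array shape does not match config size")
        self.spins = spins
        self.config = config
        self.n_labels = int(config.n_cells)
        if spins.max() > self.n_labels or spins.min() < 0:
            raise ValueError("spin labels out of range")
        self.areas = kern.compute_areas(spins, self.n_labels)
        self.perimeters = kern.compute_perimeters(spins, config.neighbors, self.n_labels)
        self.sweep = 0
        self._energy = self.recompute_energy()

    @property
    def energy(self) -> float:
        return self._energy

    def recompute_energy(self) -> float:
        """Full energy recomputation from the caches (label 0 carries none)."""
        c = self.config
        return float(
            kern.total_energy(
                self.areas, self.perimeters, c.lambda_A, c.lambda_P, c.A0, c.P0,
                self.n_labels,
            )
        )

    def verify_consistency(self, atol: float = 1e-9):
        """Check caches and incremental energy against full recomputation."""
        areas = kern.compute_areas(self.spins, self.n_labels)
        perims = kern.compute_perimeters(self.spins, self.config.neighbors, self.n_labels)
        if not np.array_equal(areas, self.areas) or not np.array_equal(
            perims, self.perimeters
        ):
            raise RuntimeError("area/perimeter caches inconsistent with lattice")
        full = kern.total_energy(
            areas, perims, self.config.lambda_A, self.config.lambda_P,
            self.config.A0, self.config.P0, self.n_labels,
        )
        if abs(full - self._energy) > atol * max(1.0, abs(full)):
            raise RuntimeError(
                f"incremental energy {self._energy} deviates from full "
                f"recomputation {full}"
            )

    def run_attempts(self, n_attempts: int) -> int:
        """Advance by raw attempted moves; returns the number accepted."""
        c = self.config
        accepted, dh = kern.run_attempts(
            self.spins, self.areas, self.perimeters, c.neighbors, c.ring,
            c.lambda_A, c.lambda_P, c.A0, c.P0, c.temperature,
            int(n_attempts), c.check_connectivity,
        )
        self._energy += dh
        return int(accepted)

    def run_sweeps(self, n_sweeps: int) -> int:
        rows, cols = self.config.size
        accepted = self.run_attempts(int(n_sweeps) * rows * cols)
        self.sweep += int(n_sweeps)
        return accepted

    # ---------------- measurement ----------------

    def _site_coords(self, label: int) -> np.ndarray:
        rr, cc = np.nonzero(self.spins == label)
        return np.column_stack([rr, cc])

    def measure_cells(self, labels=None) -> pd.DataFrame:
        """Per-cell morphometrics with periodic-aware gyration tensors.

        Coordinates are unwrapped by the minimal image relative to each
        cell's first site (cells are small compared with the box).  On the
        hexagonal lattice axial coordinates are mapped to cartesian before
        the tensor is built.
        """
        c = self.config
        rows, cols = c.size
        hexa = c.lattice == "hexagonal"
        if labels is None:
            labels = range(1, self.n_labels + 1)
        out = []
        for lab in labels:
            pts = self._site_coords(lab).astype(float)
            if pts.shape[0] == 0:
                continue
            d = pts - pts[0]
            d[:, 0] = (d[:, 0] + rows / 2.0) % rows - rows / 2.0
            d[:, 1] = (d[:, 1] + cols / 2.0) % cols - cols / 2.0
            if hexa:
                xy = np.column_stack([d[:, 1] + 0.5 * d[:, 0], _SQRT3_2 * d[:, 0]])
            else:
                xy = d
            centered = xy - xy.mean(axis=0)
            tensor = centered.T @ centered / xy.shape[0]
            corr = PIXEL_MOMENT * (_SQRT3_2 if hexa else 1.0)
            tensor[0, 0] += corr
            tensor[1, 1] += corr
            eigs = np.linalg.eigvalsh(tensor)
            s2_sq, s1_sq = float(eigs[0]), float(eigs[1])
            cen = pts[0] + d.mean(axis=0)
            out.append(
                {
                    "cell_id": int(lab),
                    "area": float(self.areas[lab]),
                    "perimeter": float(self.perimeters[lab]),
                    "s1_sq": s1_sq,
                    "s2_sq": s2_sq,
                    "aspect_ratio": float(np.sqrt(s1_sq / s2_sq)) if s2_sq > 0 else np.nan,
                    "centroid_row": float(cen[0] % rows),
                    "centroid_col": float(cen[1] % cols),
                }
            )
        return pd.DataFrame(out)


def energy(state: CPMState, config: CPMConfig | None = None) -> float:
    """Total energy of a state under the area/perimeter Hamiltonian."""
    if config is not None and config is not state.config:
        return float(
            kern.total_energy(
                state.areas, state.perimeters, config.lambda_A, config.lambda_P,
                config.A0, config.P0, state.n_labels,
            )
        )
    state.verify_consistency()
    return state.energy


def metropolis_sweep(state: CPMState, n_sweeps: int = 1) -> int:
    """Advance the state by whole Monte Carlo sweeps; returns accepted moves."""
    return state.run_sweeps(n_sweeps)


# ---------------------------------------------------------------------------
# initialization


def _hex_cartesian(rc: np.ndarray) -> np.ndarray:
    return np.column_stack([rc[:, 1] + 0.5 * rc[:, 0], _SQRT3_2 * rc[:, 0]])


def voronoi_labels(
    rows: int, cols: int, n_cells: int, rng: np.random.Generator,
    lattice: str = "square",
) -> np.ndarray:
    """Nearest-seed tessellation under the periodic metric; labels 1..n_cells.

    Seed sites are drawn without replacement.  For the hexagonal lattice the
    distance is measured in the cartesian embedding of the axial coordinates,
    minimized over the nine periodic images of the (sheared) unit cell.
    """
    sites = rows * cols
    seeds = rng.choice(sites, size=n_cells, replace=False)
    seed_rc = np.column_stack([seeds // cols, seeds % cols]).astype(float)
    grid = np.indices((rows, cols)).reshape(2, -1).T.astype(float)
    if lattice == "square":
        d = np.abs(grid[:, None, :] - seed_rc[None, :, :])
        d[..., 0] = np.minimum(d[..., 0], rows - d[..., 0])
        d[..., 1] = np.minimum(d[..., 1], cols - d[..., 1])
        dist2 = (d**2).sum(axis=-1)
    else:
        best = np.full((sites, n_cells), np.inf)
        for mi in (-1.0, 0.0, 1.0):
            for mj in (-1.0, 0.0, 1.0):
                shifted = seed_rc + np.array([mi * rows, mj * cols])
                diff = _hex_cartesian(grid)[:, None, :] - _hex_cartesian(shifted)[None, :, :]
                best = np.minimum(best, (diff**2).sum(axis=-1))
        dist2 = best
    labels = dist2.argmin(axis=1).astype(np.int64) + 1
    return labels.reshape(rows, cols)


def _single_cell_spins(config: CPMConfig) -> np.ndarray:
    """Compact near-square blob of area A0 centered on the lattice."""
    rows, cols = config.size
    spins = np.zeros((rows, cols), dtype=np.int64)
    target = int(round(config.A0))
    side = max(1, int(np.floor(np.sqrt(target))))
    r0, c0 = rows // 2 - side // 2, cols // 2 - side // 2
    filled, i = 0, 0
    while filled < target:
        width = min(side, target - filled)
        spins[(r0 + i) % rows, [(c0 + k) % cols for k in range(width)]] = 1
        filled += width
        i += 1
    return spins


# ---------------------------------------------------------------------------
# results


@dataclass
class RelaxationResult:
    tau: float
    is_lower_bound: bool
    lags: np.ndarray  # in sweeps
    q: np.ndarray


@dataclass
class SimulationResult:
    """Output of a CPM run: pooled shape samples, trajectories, diagnostics."""

    config: CPMConfig
    samples: pd.DataFrame          # per-sample per-cell morphometrics
    trajectory: np.ndarray         # (n_samples, n_cells, 2) unwrapped (row, col)
    sample_sweeps: np.ndarray      # sweep index of each sample
    energy_trace: pd.DataFrame     # columns: sweep, energy (equilibration + production)
    acceptance_rate: float
    final_spins: np.ndarray
    equilibration_drift: float = np.nan
    equilibrated: bool = True

    def ensemble(self) -> ShapeEnsemble:
        return ShapeEnsemble(
            self.samples[
                ["cell_id", "area", "perimeter", "s1_sq", "s2_sq", "aspect_ratio",
                 "centroid_row", "centroid_col"]
            ].assign(on_border=False)
        )

    def fit_alpha(self, bootstrap: int = 0, seed: int = 0):
        from .models import AspectRatioModel

        r = self.samples["aspect_ratio"].dropna().to_numpy()
        return AspectRatioModel(r).fit(bootstrap=bootstrap, seed=seed)

    def fit_mu(self, bootstrap: int = 0, seed: int = 0):
        from .models import ScaledAreaModel

        return ScaledAreaModel(self.samples["area"].to_numpy()).fit(
            bootstrap=bootstrap, seed=seed
        )

    def summary(self) -> dict:
        ens = self.ensemble()
        out = {
            "n_samples": int(self.sample_sweeps.size),
            "n_cells": int(self.config.n_cells),
            "mean_r": ens.mean_r,
            "sd_r": ens.sd_r,
            "mean_area": float(self.samples["area"].mean()),
            "acceptance_rate": self.acceptance_rate,
            "equilibration_drift": self.equilibration_drift,
        }
        try:
            out["alpha_hat"] = self.fit_alpha().params
            out["mu_hat"] = self.fit_mu().params
        except ValueError:
            pass
        return out

    def area_energy(self) -> float:
        """Time-averaged area-term energy sum_i lambda_A (A_i - A0)^2."""
        c = self.config
        per_sample = (
            c.lambda_A
            * (self.samples["area"] - c.A0) ** 2
        ).groupby(self.samples["sample"]).sum()
        return float(per_sample.mean())

    def perimeter_energy(self) -> float:
        """Time-averaged perimeter-term energy sum_i lambda_P (P_i - P0)^2."""
        c = self.config
        per_sample = (
            c.lambda_P
            * (self.samples["perimeter"] - c.P0) ** 2
        ).groupby(self.samples["sample"]).sum()
        return float(per_sample.mean())

    def relaxation(self, a0: float = 1.0) -> RelaxationResult:
        return relaxation_time(
            self.trajectory, self.sample_sweeps, a0=a0, lattice=self.config.lattice
        )

    def save(self, outdir):
        from .morphometry import write_label_image

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(outdir / "cells.csv", index=False)
        self.energy_trace.to_csv(outdir / "energy_trace.csv", index=False)
        write_label_image(outdir / "final_mask.tif", self.final_spins.astype(np.int32))
        manifest = {
            "config": self.config.to_dict(),
            "acceptance_rate": self.acceptance_rate,
            "equilibration_drift": self.equilibration_drift,
            "summary": {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                        for k, v in self.summary().items()},
        }
        (outdir / "run.json").write_text(json.dumps(manifest, indent=2, default=float))


def _wrap_delta(delta: np.ndarray, period: float) -> np.ndarray:
    return (delta + period / 2.0) % period - period / 2.0


def _run(config: CPMConfig, spins: np.ndarray, labels) -> SimulationResult:
    state = CPMState(spins, config)
    rows, cols = config.size
    kern.seed_rng(int(config.seed) & 0x7FFFFFFF)

    # equilibration with an energy-plateau diagnostic
    n_checks = 40
    chunk = max(1, config.equilibration_sweeps // n_checks)
    eq_sweeps, eq_energy = [], []
    done = 0
    while done < config.equilibration_sweeps:
        step = min(chunk, config.equilibration_sweeps - done)
        state.run_sweeps(step)
        done += step
        eq_sweeps.append(done)
        eq_energy.append(state.energy)
    drift = np.nan
    equilibrated = True
    if len(eq_energy) >= 8:
        e = np.asarray(eq_energy)
        q = len(e) // 4
        last, prev = e[-q:].mean(), e[-2 * q: -q].mean()
        drift = abs(last - prev) / max(abs(last), 1e-12)
        # a plateau is declared when the quarter-mean difference is within
        # the thermal noise of the quarter means (z < 3) or below plateau_tol
        noise = e[-2 * q:].std(ddof=1) / np.sqrt(q)
        z = abs(last - prev) / max(noise, 1e-12)
        equilibrated = drift < config.plateau_tol or z < 3.0
        if not equilibrated:
            warnings.warn(
                f"energy trace still drifting after equilibration "
                f"(relative drift {drift:.3g}, z={z:.1f}); consider more sweeps",
                RuntimeWarning,
            )

    labels = list(labels)
    n_samples = config.production_sweeps // config.sampling_interval
    frames = []
    traj = np.zeros((n_samples, len(labels), 2))
    sweeps_at = np.zeros(n_samples, dtype=int)
    accepted = 0
    attempts = 0
    prev_centroid = None
    unwrapped = None
    prod_sweeps, prod_energy = [], []
    for k in range(n_samples):
        accepted += state.run_sweeps(config.sampling_interval)
        attempts += config.sampling_interval * rows * cols
        df = state.measure_cells(labels)
        df.insert(0, "sample", k)
        df.insert(1, "sweep", state.sweep)
        frames.append(df)
        cen = df[["centroid_row", "centroid_col"]].to_numpy()
        if prev_centroid is None:
            unwrapped = cen.copy()
        else:
            step = np.column_stack(
                [_wrap_delta(cen[:, 0] - prev_centroid[:, 0], rows),
                 _wrap_delta(cen[:, 1] - prev_centroid[:, 1], cols)]
            )
            unwrapped = unwrapped + step
        prev_centroid = cen
        traj[k] = unwrapped
        sweeps_at[k] = state.sweep
        prod_sweeps.append(state.sweep)
        prod_energy.append(state.energy)

    state.verify_consistency()
    samples = pd.concat(frames, ignore_index=True)
    # confluency / conservation invariant
    if labels == list(range(1, config.n_cells + 1)) and spins.min() >= 1:
        assert int(state.areas[1:].sum()) == rows * cols
    trace = pd.DataFrame(
        {"sweep": eq_sweeps + prod_sweeps, "energy": eq_energy + prod_energy,
         "phase": ["equilibration"] * len(eq_sweeps) + ["production"] * len(prod_sweeps)}
    )
    return SimulationResult(
        config=config,
        samples=samples,
        trajectory=traj,
        sample_sweeps=sweeps_at,
        energy_trace=trace,
        acceptance_rate=accepted / max(attempts, 1),
        final_spins=state.spins.copy(),
        equilibration_drift=float(drift),
        equilibrated=equilibrated,
    )


def run_simulation(config: CPMConfig) -> SimulationResult:
    """Confluent run: Voronoi initialization, equilibration, sampling."""
    rng = np.random.default_rng(config.seed)
    rows, cols = config.size
    spins = voronoi_labels(rows, cols, config.n_cells, rng, config.lattice)
    return _run(config, spins, range(1, config.n_cells + 1))


def single_cell_mode(config: CPMConfig) -> SimulationResult:
    """One cell in medium (label 0, no energy terms); same sampling protocol."""
    if config.n_cells != 1:
        raise ValueError("single_cell_mode requires n_cells == 1")
    spins = _single_cell_spins(config)
    return _run(config, spins, [1])


def relaxation_time(
    trajectory: np.ndarray,
    sample_sweeps: np.ndarray,
    a0: float = 1.0,
    lattice: str = "square",
) -> RelaxationResult:
    """Relaxation time from the self-overlap function.

    Q(t) = (1/N) sum_i theta(a0 - |dr_i(t)|), averaged over time origins; tau
    solves Q(tau) = 1/e by log-time interpolation.  The default overlap
    length a0 is one lattice unit.  If Q never decays below 1/e the returned
    tau is infinite (frozen trajectory) or the largest available lag (flagged
    as a lower bound).
    """
    traj = np.asarray(trajectory, dtype=float)
    sweeps = np.asarray(sample_sweeps)
    if traj.ndim != 3 or traj.shape[0] != sweeps.size:
        raise ValueError("trajectory must be (n_samples, n_cells, 2)")
    n = traj.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    if lattice == "hexagonal":
        xy = np.empty_like(traj)
        xy[..., 0] = traj[..., 1] + 0.5 * traj[..., 0]
        xy[..., 1] = _SQRT3_2 * traj[..., 0]
        traj = xy
    dt = sweeps[1] - sweeps[0]
    lags = np.arange(1, n) * dt
    q = np.empty(n - 1)
    for k in range(1, n):
        disp = traj[k:] - traj[:-k]
        q[k - 1] = float(np.mean(np.hypot(disp[..., 0], disp[..., 1]) < a0))
    target = 1.0 / np.e
    below = np.nonzero(q < target)[0]
    if below.size == 0:
        frozen = np.allclose(traj[-1], traj[0])
        return RelaxationResult(
            tau=np.inf if frozen or q[-1] >= 0.999 else float(lags[-1]),
            is_lower_bound=True, lags=lags, q=q,
        )
    k = below[0]
    if k == 0:
        tau = float(lags[0])
    else:
        lt1, lt2 = np.log(lags[k - 1]), np.log(lags[k])
        q1, q2 = q[k - 1], q[k]
        tau = float(np.exp(lt1 + (lt2 - lt1) * (q1 - target) / (q1 - q2)))
    return RelaxationResult(tau=tau, is_lower_bound=False, lags=lags, q=q)
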