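"""Polarizability over coordinate frames and across conformational states.

A trajectory here is just an ordered list of structures (PDB MODEL blocks,
a directory of files, or synthetic thermal frames).  Frames are processed
independently, so results do not depend on evaluation order.  No alignment
or superposition is performed: rigid rotation is *signal* for the
direction-resolved polarizability vector magnitudes (a freely tumbling
molecule modulates its scattering), while the eigenvalue-average
polarizability is rotation-invariant and tracks conformation only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dipole_model import DEFAULT_TOL, PolarizabilityResult, compute_polarizability
from .errors import PolscatError, ValidationError
from .optics import (MediumModel, OpticalConfig, excess_polarizability,
                     min_intensity_w_per_um2)
from .structures import (AtomicStructure, PolarizabilityTable,
                         assign_polarizabilities)

_CHANNELS = ("alpha_ex_avg", "alpha_ex_x", "alpha_ex_y", "alpha_ex_z")


@dataclass
class PolarizabilityTimeSeries:
    """Per-frame excess polarizability channels (A^3)."""

    times: np.ndarray
    alpha_ex_avg: np.ndarray
    alpha_ex_vec: np.ndarray  # (n_frames, 3): ||alpha_ex,k|| for k = x, y, z
    alpha_m: float
    provenance: list[str]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.alpha_ex_avg = np.asarray(self.alpha_ex_avg, dtype=float)
        self.alpha_ex_vec = np.asarray(self.alpha_ex_vec, dtype=float)
        n = len(self.times)
        if not (len(self.alpha_ex_avg) == n and self.alpha_ex_vec.shape == (n, 3)):
            raise ValidationError("series channels must have equal lengths")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "alpha_ex_avg": self.alpha_ex_avg,
            "alpha_ex_x": self.alpha_ex_vec[:, 0],
            "alpha_ex_y": self.alpha_ex_vec[:, 1],
            "alpha_ex_z": self.alpha_ex_vec[:, 2],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def polarizability_series(frames: list[AtomicStructure],
                          table: PolarizabilityTable | None = None,
                          medium: MediumModel | float = 0.0,
                          threshold_radius: float | None = None,
                          solver: str = "auto", tol: float = DEFAULT_TOL,
                          times=None, dt: float = 1.0
                          ) -> PolarizabilityTimeSeries:
    """One polarizability + medium subtraction per frame.

    ``times`` overrides the frame times; otherwise uniform spacing ``dt``
    is assumed.  A constant medium polarizability is subtracted from every
    frame.  A failing frame aborts with its index attached.
    """
    if not frames:
        raise ValidationError("need at least one frame")
    counts = {f.n_atoms for f in frames}
    if len(counts) > 1:
        warnings.warn(f"inconsistent atom counts across frames: {sorted(counts)}",
                      RuntimeWarning, stacklevel=2)
    if times is None:
        times = np.arange(len(frames)) * dt
    times = np.asarray(times, dtype=float)
    if len(times) != len(frames):
        raise ValidationError("times length must match number of frames")

    avg = np.empty(len(frames))
    vec = np.empty((len(frames), 3))
    for idx, frame in enumerate(frames):
        try:
            system = assign_polarizabilities(frame, table,
                                             threshold_radius=threshold_radius)
            result = compute_polarizability(system, solver=solver, tol=tol)
            ex = excess_polarizability(result, medium)
        except PolscatError as exc:
            raise type(exc)(f"frame {idx}: {exc}") from exc
        avg[idx] = ex.alpha_ex_avg
        vec[idx] = ex.vector_magnitudes_ex
    alpha_m = medium.alpha_m if isinstance(medium, MediumModel) else float(medium)
    return PolarizabilityTimeSeries(
        times=times, alpha_ex_avg=avg, alpha_ex_vec=vec, alpha_m=alpha_m,
        provenance=[f.source for f in frames])


@dataclass
class ChannelStats:
    mean: float
    percent_range: float          # 100 * (max - min) / mean
    percent_std: float            # 100 * sample std / mean
    standard_error_percent: float  # percent_std / sqrt(n)


@dataclass
class FluctuationSummary:
    """Spread statistics of each series channel, in percent of its mean.

    The standard error (sample std / sqrt(n), as a percent of the mean)
    reads as the relative uncertainty of the time-averaged polarizability
    under a Gaussian-fluctuation assumption.
    """

    n_frames: int
    channels: dict

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "channels": {
                name: {
                    "mean_A3": s.mean,
                    "percent_range": s.percent_range,
                    "percent_std": s.percent_std,
                    "standard_error_percent": s.standard_error_percent,
                } for name, s in self.channels.items()},
        }


def summarize_fluctuations(series: PolarizabilityTimeSeries
                           ) -> FluctuationSummary:
    """Mean, percent range, percent std and SEM of every channel."""
    n = series.n_frames
    if n < 2:
        raise ValidationError("need at least 2 frames for spread statistics")
    frame = series.to_frame()
    channels = {}
    for name in _CHANNELS:
        x = frame[name].to_numpy()
        mean = float(x.mean())
        if mean == 0:
            raise ValidationError(f"channel {name} has zero mean")
        std = float(x.std(ddof=1))
        channels[name] = ChannelStats(
            mean=mean,
            percent_range=100.0 * float(x.max() - x.min()) / abs(mean),
            percent_std=100.0 * std / abs(mean),
            standard_error_percent=100.0 * std / abs(mean) / np.sqrt(n),
        )
    return FluctuationSummary(n_frames=n, channels=channels)


@dataclass
class StatePair:
    """Signed percent changes from state a to state b (base = state a)."""

    name_a: str
    name_b: str
    percent_change_avg: float
    percent_change_vec: np.ndarray  # per field direction x, y, z
    i_min_w_per_um2: np.ndarray | None  # per direction, if optics configured


@dataclass
class StateComparison:
    names: list[str]
    results: dict              # name -> PolarizabilityResult
    excess: dict               # name -> ExcessPolarizability
    pairs: list[StatePair]

    def to_dict(self) -> dict:
        out = {"states": {}, "pairs": []}
        for name in self.names:
            ex = self.excess[name]
            out["states"][name] = {
                "alpha_ex_avg_A3": ex.alpha_ex_avg,
                "alpha_ex_vector_magnitudes_A3": {
                    k: float(ex.vector_magnitudes_ex[i])
                    for i, k in enumerate("xyz")},
            }
        for p in self.pairs:
            entry = {
                "from": p.name_a, "to": p.name_b,
                "percent_change_alpha_ex_avg": p.percent_change_avg,
                "percent_change_alpha_ex_vec": {
                    k: float(p.percent_change_vec[i])
                    for i, k in enumerate("xyz")},
            }
            if p.i_min_w_per_um2 is not None:
                entry["I_min_W_per_um2"] = {
                    k: float(p.i_min_w_per_um2[i]) for i, k in enumerate("xyz")}
            out["pairs"].append(entry)
        return out


def compare_states(states: list[tuple[str, AtomicStructure]],
                   table: PolarizabilityTable | None = None,
                   medium: MediumModel | float = 0.0,
                   threshold_radius: float | None = None,
                   solver: str = "auto", tol: float = DEFAULT_TOL,
                   config: OpticalConfig | None = None,
                   taus: tuple[float, float] | None = None,
                   i_min_mode: str = "printed") -> StateComparison:
    """Compare discrete conformational states of a molecule.

    Structures are used in their own file coordinate frames (axes as in the
    deposited coordinates).  Percent changes are reported for consecutive
    pairs, closing the cycle when more than two states are given.  If an
    optical config and per-state integration times are supplied, the
    minimum resolving intensity for each pair is computed from the
    direction-resolved excess polarizability magnitudes.
    """
    if len(states) < 2:
        raise ValidationError("need at least 2 states to compare")
    names = [name for name, _ in states]
    if len(set(names)) != len(names):
        raise ValidationError("state names must be unique")

    results: dict[str, PolarizabilityResult] = {}
    excess = {}
    for name, structure in states:
        system = assign_polarizabilities(structure, table,
                                         threshold_radius=threshold_radius)
        res = compute_polarizability(system, solver=solver, tol=tol)
        results[name] = res
        excess[name] = excess_polarizability(res, medium)

    pair_index = list(zip(range(len(names) - 1), range(1, len(names))))
    if len(names) > 2:
        pair_index.append((len(names) - 1, 0))  # close the cycle

    pairs = []
    for ia, ib in pair_index:
        na, nb = names[ia], names[ib]
        ea, eb = excess[na], excess[nb]
        pct_avg = 100.0 * (eb.alpha_ex_avg - ea.alpha_ex_avg) / ea.alpha_ex_avg
        pct_vec = 100.0 * (eb.vector_magnitudes_ex - ea.vector_magnitudes_ex) \
            / ea.vector_magnitudes_ex
        i_min = None
        if config is not None and taus is not None:
            tau_a, tau_b = taus
            i_min = np.array([
                min_intensity_w_per_um2(ea.vector_magnitudes_ex[k],
                                        eb.vector_magnitudes_ex[k],
                                        tau_a, tau_b, config, mode=i_min_mode)
                for k in range(3)])
        pairs.append(StatePair(name_a=na, name_b=nb,
                               percent_change_avg=float(pct_avg),
                               percent_change_vec=pct_vec,
                               i_min_w_per_um2=i_min))
    return StateComparison(names=names, results=results, excess=excess,
                           pairs=pairs)
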