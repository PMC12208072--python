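"""Langevin translocation dynamics and synthetic barcode traces.

DNA translocating through a solid-state nanopore under a bias voltage is
described, in one dimension, by the Langevin equation

    m dv/dt + alpha v - F = A(t),        F = V_b * lambda,

balancing inertia, drag, the electric driving force and a stochastic thermal
force.  A refinement treats the DNA as an unraveling chain whose effective
mass m(t) and drag alpha(t) change as the molecule feeds through the pore.
The simulators here integrate both forms with an explicit Euler-Maruyama
scheme (overdamped closed form when m = 0) and are dimensionless by default:
the source model gives no units or magnitudes, and only the qualitative
statistics — white velocity noise, Brownian growth of the position variance —
matter for the augmentation they motivate.

The second half of the module synthesizes labeled barcode traces with the
structure of real 3-bit DNA-barcode nanopore events: a baseline at 0, a
negative-going translocation drop, two flanking indicator dips, a dip per set
bit, optional folding artifacts, random read direction and additive noise,
zero-padded to a fixed length L (700 by default).  Traces are generated
already normalized: the unfolded-DNA current drop is 1 in magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .augment import _as_rng

__all__ = [
    "LangevinParams",
    "UnravelingSchedule",
    "Trajectory",
    "BarcodeSpec",
    "Trace",
    "integrate_langevin",
    "integrate_unraveling",
    "synthesize_trace",
    "synthesize_dataset",
    "decode_bits",
    "stack_traces",
]


@dataclass(frozen=True)
class LangevinParams:
    """Physical parameters of the translocation model (dimensionless units).

    ``mass = 0`` selects the overdamped limit, where the velocity responds
    instantaneously: ``v = (F + A) / drag``.  ``thermal_intensity`` is the
    standard deviation of the discretized thermal force per step.
    """

    drag: float
    mass: float = 0.0
    bias_voltage: float = 1.0
    charge_density: float = 1.0
    thermal_intensity: float = 0.0
    dt: float = 1e-2

    def __post_init__(self) -> None:
        vals = (self.drag, self.mass, self.bias_voltage, self.charge_density,
                self.thermal_intensity, self.dt)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all Langevin parameters must be finite")
        if self.mass == 0 and self.drag == 0:
            raise ValueError("mass = 0 with drag = 0 leaves the velocity undefined")
        if self.drag <= 0:
            raise ValueError(f"drag must be > 0, got {self.drag}")
        if self.mass < 0:
            raise ValueError(f"mass must be >= 0, got {self.mass}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.thermal_intensity < 0:
            raise ValueError(f"thermal_intensity must be >= 0, got {self.thermal_intensity}")

    @property
    def force(self) -> float:
        """Driving force F = V_b * lambda."""
        return self.bias_voltage * self.charge_density


@dataclass(frozen=True)
class UnravelingSchedule:
    """Instantaneous mass and drag as functions of the translocated fraction.

    The exact chain-segment calculation lives in the polymer-physics
    literature; the affine default here is an explicit stand-in capturing its
    qualitative shape (drag falling as the chain unravels, or rising, as
    configured) and is flagged as such in the methods note.
    """

    mass_fn: Callable[[float], float]
    drag_fn: Callable[[float], float]

    def validate(self, n_probe: int = 21) -> None:
        for f in np.linspace(0.0, 1.0, n_probe):
            a, m = self.drag_fn(float(f)), self.mass_fn(float(f))
            if not (np.isfinite(a) and a > 0):
                raise ValueError(f"drag_fn must be finite and > 0 on [0,1]; got {a} at {f}")
            if not (np.isfinite(m) and m >= 0):
                raise ValueError(f"mass_fn must be finite and >= 0 on [0,1]; got {m} at {f}")

    @classmethod
    def constant(cls, mass: float, drag: float) -> "UnravelingSchedule":
        return cls(mass_fn=lambda f: mass, drag_fn=lambda f: drag)

    @classmethod
    def affine_drag(cls, drag_start: float, drag_end: float, mass: float = 0.0) -> "UnravelingSchedule":
        """Drag affine in the translocated fraction, constant mass."""
        return cls(mass_fn=lambda f: mass,
                   drag_fn=lambda f: drag_start + (drag_end - drag_start) * f)


@dataclass(frozen=True)
class Trajectory:
    """Integrated translocation path.

    ``positions[0] = 0`` and ``positions[k+1] - positions[k] =
    velocities[k+1] * dt`` (the integration identity); both arrays have the
    same length, ``n_steps + 1``.
    """

    positions: np.ndarray
    velocities: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.velocities):
            raise ValueError("positions and velocities must have equal length")

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1

    @property
    def duration(self) -> float:
        """Total integrated time."""
        return self.n_steps * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) * self.dt


def integrate_langevin(params: LangevinParams, n_steps: int, seed=None,
                       v0: float = 0.0) -> Trajectory:
    """Integrate the constant-coefficient Langevin equation.

    Euler-Maruyama: ``v[k+1] = v[k] + (dt/m)(F - drag*v[k] + A_k)`` with the
    thermal force ``A_k ~ N(0, thermal_intensity)`` i.i.d. per step; in the
    overdamped limit (``mass = 0``), ``v[k] = (F + A_k) / drag``.  Positions
    are cumulative sums of ``v dt`` starting at 0.  Identical seeds give
    identical trajectories.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    rng = _as_rng(seed)
    F, a, m, dt = params.force, params.drag, params.mass, params.dt
    A = rng.normal(0.0, params.thermal_intensity, size=n_steps)
    v = np.empty(n_steps + 1, dtype=float)
    if m == 0:
        v[0] = F / a
        v[1:] = (F + A) / a
    else:
        v[0] = v0
        c = dt / m
        for k in range(n_steps):
            v[k + 1] = v[k] + c * (F - a * v[k] + A[k])
    positions = np.empty(n_steps + 1, dtype=float)
    positions[0] = 0.0
    np.cumsum(v[1:] * dt, out=positions[1:])
    return Trajectory(positions=positions, velocities=v, dt=dt)


def integrate_unraveling(params: LangevinParams, schedule: UnravelingSchedule,
                         chain_length: float, seed=None, v0: float = 0.0,
                         max_steps: int = 1_000_000) -> Trajectory:
    """Integrate the unraveling-chain Langevin equation.

    As :func:`integrate_langevin` but mass and drag are re-evaluated each
    step from the schedule at the translocated fraction ``position /
    chain_length`` (clamped to [0, 1]).  Integration stops once the position
    reaches ``chain_length``, or at ``max_steps``.
    """
    if not chain_length > 0:
        raise ValueError(f"chain_length must be > 0, got {chain_length}")
    schedule.validate()
    rng = _as_rng(seed)
    F, dt, sigma_A = params.force, params.dt, params.thermal_intensity
    m0 = schedule.mass_fn(0.0)
    positions = [0.0]
    velocities = [F / schedule.drag_fn(0.0) if m0 == 0 else v0]
    x = 0.0
    v = velocities[0]
    for _ in range(max_steps):
        frac = min(x / chain_length, 1.0)
        a = schedule.drag_fn(frac)
        m = schedule.mass_fn(frac)
        A = rng.normal(0.0, sigma_A) if sigma_A > 0 else 0.0
        if m == 0:
            v = (F + A) / a
        else:
            v = v + (dt / m) * (F - a * v + A)
        x += v * dt
        velocities.append(v)
        positions.append(x)
        if x >= chain_length:
            break
    return Trajectory(positions=np.asarray(positions), velocities=np.asarray(velocities), dt=dt)


# ---------------------------------------------------------------------------
# synthetic barcode traces


@dataclass(frozen=True)
class BarcodeSpec:
    """Morphology of a synthetic 3-bit barcode translocation event.

    Depths are in normalized current units (the unfolded-DNA drop is
    ``base_drop``, 1.0 by default, so the event plateau sits at -1); widths
    and lengths are in samples.  The two indicator dips flank the barcode
    region; a dip in bit slot j is present iff ``bits[j] = 1``.
    """

    bits: tuple
    event_length: int = 400
    dip_depth: float = 0.5
    dip_width: int = 20
    indicator_depth: float = 0.5
    indicator_width: int = 20
    base_drop: float = 1.0
    fold_prob: float = 0.1
    reverse_prob: float = 0.5
    noise_std: float = 0.05

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if len(bits) != 3 or any(b not in (0, 1) for b in bits):
            raise ValueError(f"bits must be 3 binary digits, got {self.bits}")
        object.__setattr__(self, "bits", bits)
        for name in ("event_length", "dip_width", "indicator_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dip_depth", "indicator_depth", "base_drop", "noise_std"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fold_prob", "reverse_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    @property
    def label(self) -> int:
        """The bits read as a 3-bit integer, most significant bit first."""
        b = self.bits
        return (b[0] << 2) | (b[1] << 1) | b[2]


@dataclass
class Trace:
    """A fixed-length normalized-current trace with its metadata."""

    samples: np.ndarray
    label: int
    experiment_id: int = -1
    event_span: tuple = (0, 0)  # half-open [start, stop) sample indices

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        s, e = self.event_span
        if not (0 <= s <= e <= len(self.samples)):
            raise ValueError(f"event_span {self.event_span} outside [0, {len(self.samples)})")


def _slot_windows(spec: BarcodeSpec):
    """Relative [start, stop) windows of the two indicators and 3 bit dips."""
    E, iw, dw = spec.event_length, spec.indicator_width, spec.dip_width
    inner_start, inner_stop = iw, E - iw
    W = inner_stop - inner_start
    if W < 3 * dw or W <= 0:
        raise ValueError(
            f"dip_width {dw} too large: bit dips would overlap the indicator dips "
            f"(inner region {W} samples, needs >= {3 * dw})")
    slots = []
    for j in range(3):
        lo = inner_start + (j * W) // 3
        hi = inner_start + ((j + 1) * W) // 3
        c = (lo + hi) // 2
        slots.append((c - dw // 2, c - dw // 2 + dw))
    indicators = [(0, iw), (E - iw, E)]
    return indicators, slots


def synthesize_trace(spec: BarcodeSpec, L: int = 700, seed=None,
                     start: int | None = None) -> Trace:
    """Synthesize one normalized barcode trace of length ``L``.

    Baseline 0 outside the event; inside, a drop of ``base_drop`` with the
    two indicator dips at the event ends and a dip per set bit.  With
    probability ``fold_prob`` a contiguous sub-segment is deepened by
    ``base_drop`` (a folded strand doubles the blockade); with probability
    ``reverse_prob`` the event is time-reversed (the molecule read backwards
    — the label stays defined on the forward read).  Gaussian noise of
    ``noise_std`` is added over the whole trace.  Deterministic under a fixed
    seed.

    As in the real padded dataset, the event sits at the head of the array
    (small random onset jitter) and the tail is zero-padding; pass ``start``
    to place it explicitly.
    """
    E = spec.event_length
    if E + 2 > L:
        raise ValueError(f"event_length {E} plus margins exceeds trace length {L}")
    rng = _as_rng(seed)
    indicators, slots = _slot_windows(spec)

    if start is None:
        start = int(rng.integers(0, min(20, L - E) + 1))
    if not 0 <= start <= L - E:
        raise ValueError(f"event start {start} leaves no room for the event")

    ev = np.full(E, -spec.base_drop, dtype=float)
    for lo, hi in indicators:
        ev[lo:hi] -= spec.indicator_depth
    for j, (lo, hi) in enumerate(slots):
        if spec.bits[j]:
            ev[lo:hi] -= spec.dip_depth

    if rng.random() < spec.fold_prob:
        flen = int(rng.integers(max(E // 8, 1), max(E // 2, 2)))
        fstart = int(rng.integers(0, E - flen + 1))
        ev[fstart:fstart + flen] -= spec.base_drop

    if rng.random() < spec.reverse_prob:
        ev = ev[::-1]

    samples = np.zeros(L, dtype=float)
    samples[start:start + E] = ev
    if spec.noise_std > 0:
        samples += rng.normal(0.0, spec.noise_std, size=L)
    return Trace(samples=samples, label=spec.label, event_span=(start, start + E))


def decode_bits(samples, spec: BarcodeSpec) -> tuple:
    """Rule-based dip counter: read the 3 bits from a clean noiseless trace.

    Finds dip regions by a run-length scan below ``-(base_drop +
    min(dip_depth, indicator_depth)/2)``, takes the first and last as the
    indicators, splits the region between them into three equal slots and
    sets bit j iff an intermediate dip center falls in slot j.  Bits are
    returned in signal (left-to-right) order, so a time-reversed event
    decodes to the reversed pattern.  Intended for noiseless, unfolded
    traces (the oracle side of the label/dip-pattern bijection).
    """
    samples = np.asarray(samples, dtype=float)
    depth = min(spec.dip_depth, spec.indicator_depth)
    thresh = -(spec.base_drop + depth / 2.0)
    below = samples < thresh
    if not below.any():
        raise ValueError("no dips found below threshold; is this a clean event trace?")
    # run-length scan of contiguous below-threshold regions
    d = np.diff(below.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        stops.append(len(samples))
    regions = list(zip(starts, stops))
    if len(regions) < 2:
        raise ValueError(f"expected at least the 2 indicator dips, found {len(regions)} region(s)")
    centers = [(lo + hi) / 2.0 for lo, hi in regions]
    inner_lo = regions[0][1]     # end of the first indicator
    inner_hi = regions[-1][0]    # start of the last indicator
    W = inner_hi - inner_lo
    slot_centers = [inner_lo + (j + 0.5) * W / 3.0 for j in range(3)]
    bits = [0, 0, 0]
    for c in centers[1:-1]:
        j = int(np.argmin([abs(c - sc) for sc in slot_centers]))
        bits[j] = 1
    return tuple(bits)


def synthesize_dataset(n_per_class: Sequence[int], n_experiments: int,
                       spec_template: BarcodeSpec | None = None,
                       experiment_jitter: float = 0.1, L: int = 700,
                       seed=None) -> list:
    """Generate a labeled multi-experiment dataset of synthetic traces.

    Each experiment carries systematic offsets — dip depth, noise level and
    event length scaled by ``1 + experiment_jitter * N(0,1)``, shared by all
    its traces — so experiment identity is statistically detectable.  This
    emulates the pore-to-pore confound that the experiment-held-out split
    protocol guards against.  Traces are assigned to experiments round-robin
    within each class (seeded order), so per-label experiment shares are
    near-equal.  All randomness flows from the single seed via one
    independent substream per trace.
    """
    n_per_class = list(n_per_class)
    if len(n_per_class) != 8:
        raise ValueError(f"n_per_class must list 8 class counts, got {len(n_per_class)}")
    if any(n < 0 for n in n_per_class):
        raise ValueError(f"class counts must be >= 0, got {n_per_class}")
    if n_experiments < 2:
        raise ValueError("need >= 2 experiments so an experiment-held-out split exists")
    if spec_template is None:
        spec_template = BarcodeSpec(bits=(0, 0, 0))

    root = SeedSequence(seed) if not isinstance(seed, SeedSequence) else seed
    exp_ss, assign_ss, trace_ss = root.spawn(3)

    exp_rng = default_rng(exp_ss)
    depth_scale = np.clip(1.0 + experiment_jitter * exp_rng.normal(size=n_experiments), 0.2, None)
    noise_scale = np.clip(1.0 + experiment_jitter * exp_rng.normal(size=n_experiments), 0.0, None)
    length_scale = np.clip(1.0 + experiment_jitter * exp_rng.normal(size=n_experiments), 0.5, None)

    assign_rng = default_rng(assign_ss)
    total = sum(n_per_class)
    children = trace_ss.spawn(total)

    traces: list[Trace] = []
    idx = 0
    for cls in range(8):
        bits = ((cls >> 2) & 1, (cls >> 1) & 1, cls & 1)
        n = n_per_class[cls]
        perm = assign_rng.permutation(n_experiments)
        exps = np.tile(perm, -(-n // n_experiments))[:n] if n else np.empty(0, int)
        for e in exps:
            e = int(e)
            ev_len = int(round(spec_template.event_length * length_scale[e]))
            ev_len = min(ev_len, L - 2)
            spec = replace(
                spec_template, bits=bits, event_length=ev_len,
                dip_depth=spec_template.dip_depth * depth_scale[e],
                indicator_depth=spec_template.indicator_depth * depth_scale[e],
                noise_std=spec_template.noise_std * noise_scale[e])
            tr = synthesize_trace(spec, L=L, seed=children[idx])
            tr.experiment_id = e
            traces.append(tr)
            idx += 1
    return traces


def stack_traces(traces: Sequence[Trace]):
    """Stack a trace list into (X float32 [N, L], labels int8, experiment_ids int32)."""
    X = np.stack([t.samples for t in traces]).astype(np.float32)
    labels = np.array([t.label for t in traces], dtype=np.int8)
    exps = np.array([t.experiment_id for t in traces], dtype=np.int32)
    return X, labels, exps
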