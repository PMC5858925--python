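"""Stochastic simulator of the translocase mechanochemical cycle on a tether.

This module is the synthetic stand-in for optical-tweezer experiments on an
ultra-fast ring-ATPase DNA translocase. A continuous-time Markov (Gillespie)
simulation of the subunit cycle is coupled to a worm-like-chain (WLC) DNA
tether held either in a fixed optical trap (*passive mode*, force rises as
the motor reels in DNA) or under force feedback (*constant-force mode*).

The subunit cycle follows the renewal abstraction of the hexamer:

    apo (awaiting ATP) --α·[ATP]--> ATP docked --k2--> tightly bound
        --k_L(F)--> --k0_rest--> [Pi-release power stroke, k_H(F)]
        --> +step_size bp, back to apo

with three off-pathway features:

* **ADP competition** — the apo subunit can bind ADP and must release it
  before ATP can dock; detailed balance with a fixed dissociation constant
  makes the mean waiting time (1 + [ADP]/K_d)/(α·[ATP]), i.e. exact
  competitive inhibition of ATP binding.
* **Pausing** — from the awaiting-ATP state the motor can enter an
  off-pathway pause (rate ``pause_entry``); it exits by binding nucleotide
  (rate ``pause_exit_rate·[ATP]``), so pause durations are exponential with
  mean inversely proportional to [ATP].
* **Slipping** — during the single-grip hand-over window (awaiting ATP,
  before the next subunit engages) the motor can lose its grip with a
  force-activated hazard ``slip_hazard0·exp(F·slip_dx/kBT)``; a slip
  releases an exponentially distributed length of contour and the force
  re-equilibrates. While a subunit is nucleotide-bound (or the motor sits in
  the two-subunit-grip pause state) the hazard is multiplied by
  ``slip_suppression``.

With pausing and slipping switched off, the mean pause-free velocity matches
the closed-form linear two-transition model exactly (same lumped rates), and
the per-cycle dwell decomposition mirrors its cycle-time terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .energetics import (
    ATP_HYDROLYSIS_PN_NM,
    BP_RISE_NM,
    DEFAULT_SCALE,
    ThermalScale,
)
from .fv_models import default_linear_params

__all__ = [
    "CycleConfig",
    "TetherTrapConfig",
    "EventLog",
    "Trace",
    "wlc_force",
    "wlc_relative_extension",
    "wlc_extension",
    "simulate_cycle_dwells",
    "simulate_trace",
    "render_trace",
    "generate_experiment",
]

#: ADP dissociation constant of the apo site, μM.
ADP_KD_UM = 129.0


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleConfig:
    """Full parameterization of the subunit mechanochemical cycle.

    Defaults reproduce the calibrated linear-model velocity surface:
    ``1/k2 + 1/k0_rest = 1/k0`` of the closed form, and ``alpha``, ``kL0``,
    ``beta``, ``dxL``, ``kH0``, ``dxH`` are taken from the calibration.
    Rates in 1/s, second-order rates in 1/(s·μM), distances in nm.
    """

    atp: float = 3000.0
    adp: float = 0.0
    pi: float = 0.0
    step_size: float = 2.0
    alpha: float = 0.0            # 0 -> calibrated default
    k_unbind: float = 0.0         # ATP undocking (0 = docking commits)
    adp_binding: float = 10.0     # ADP on-rate; off-rate = adp_binding * K_d
    adp_kd: float = ADP_KD_UM
    tight_binding: float = 0.0    # k2; 0 -> 2*k0 of the calibrated default
    kL0: float = 0.0
    beta: float = 0.0
    dxL: float = 0.0
    kH0: float = 0.0
    dxH: float = 0.0
    k0_rest: float = 0.0          # 0 -> 2*k0 of the calibrated default
    pause_entry: float = 0.0      # 1/s from the awaiting-ATP state
    pause_exit_rate: float = 0.012  # 1/(s·μM), exit = rate * [ATP]
    slip_hazard0: float = 0.0     # 1/s at zero force
    slip_dx: float = 0.3          # nm, force activation of slipping
    slip_suppression: float = 0.0  # hazard multiplier outside the grip window
    slip_mean_bp: float = 500.0   # mean released contour per slip
    energy_budget: float = ATP_HYDROLYSIS_PN_NM  # pN·nm per ATP
    seed: int = 0

    def resolved(self) -> "CycleConfig":
        """Fill zero-valued kinetic fields from the calibrated linear model."""
        lin = default_linear_params()
        updates: dict[str, float] = {}
        if self.alpha == 0.0:
            updates["alpha"] = float(lin.alpha)
        if self.kL0 == 0.0:
            updates.update(kL0=float(lin.kL0), beta=float(lin.beta), dxL=lin.dxL)
        if self.kH0 == 0.0:
            updates.update(kH0=float(lin.kH0), dxH=lin.dxH)
        if self.tight_binding == 0.0:
            updates["tight_binding"] = 2.0 * float(lin.k0)
        if self.k0_rest == 0.0:
            updates["k0_rest"] = 2.0 * float(lin.k0)
        cfg = replace(self, **updates) if updates else self
        if cfg.atp <= 0:
            raise ConfigurationError("atp must be positive")
        if min(cfg.adp, cfg.pi) < 0 or cfg.step_size <= 0:
            raise ConfigurationError("invalid concentrations or step size")
        for name in ("alpha", "tight_binding", "kL0", "kH0", "k0_rest",
                     "pause_exit_rate"):
            if getattr(cfg, name) <= 0:
                raise ConfigurationError(f"{name} must be positive after resolution")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TetherTrapConfig:
    """Tether mechanics, trap and measurement parameters.

    ``contour_length0`` in bp; ``persistence_length`` in nm;
    ``stretch_modulus`` in pN (None = inextensible); ``trap_stiffness`` in
    pN/nm; ``sample_rate`` in Hz; ``noise_sd`` Gaussian noise on measured
    extension, nm. Passive mode starts at ``initial_force`` pN.
    """

    contour_length0: float = 40000.0
    persistence_length: float = 50.0
    stretch_modulus: float | None = None
    trap_stiffness: float = 0.1
    mode: str = "constant_force"
    setpoint_force: float | None = 5.0
    initial_force: float = 3.0
    sample_rate: float = 2500.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.persistence_length <= 0 or self.sample_rate <= 0:
            raise ConfigurationError("persistence_length and sample_rate must be > 0")
        if self.mode not in ("passive", "constant_force"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "constant_force" and (
            self.setpoint_force is None or self.setpoint_force <= 0
        ):
            raise ConfigurationError("constant_force mode requires a positive setpoint_force")
        if self.mode == "passive" and self.setpoint_force is not None:
            raise ConfigurationError("setpoint_force is only valid in constant_force mode")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EventLog:
    """Ground-truth pause/slip/step events of one simulated trace."""

    pauses: list[tuple[float, float, float]] = field(default_factory=list)
    slips: list[tuple[float, float, float]] = field(default_factory=list)
    steps: list[tuple[float, float]] = field(default_factory=list)

    def pause_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pauses, columns=["start_s", "duration_s", "force_pN"])

    def slip_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.slips, columns=["time_s", "released_bp", "force_before_pN"]
        )

    def step_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["time_s", "size_bp"])


@dataclass
class Trace:
    """Sampled trace: observed extension/force plus the noise-free contour."""

    time: np.ndarray          # s
    extension: np.ndarray     # nm (with measurement noise)
    force: np.ndarray         # pN
    contour_length: np.ndarray  # bp, noise-free ground-truth channel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.extension) == len(self.force) == len(self.contour_length) == n):
            raise ValueError("trace channels must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "extension_nm": self.extension,
                "force_pN": self.force,
                "contour_bp": self.contour_length,
            }
        )


# --------------------------------------------------------------------------
# worm-like chain
# --------------------------------------------------------------------------

def wlc_force(
    extension: float,
    contour: float,
    persistence: float,
    scale: ThermalScale = DEFAULT_SCALE,
    stretch_modulus: float | None = None,
) -> float:
    """Marko-Siggia interpolation force (pN) at a given extension (nm).

    ``F = (kBT/P)·[1/(4(1-z)²) - 1/4 + z]`` with ``z = x/L``; with a finite
    stretch modulus S the relative extension is ``x/L - F/S``, solved
    self-consistently.
    """
    if contour <= 0:
        raise ValueError("contour must be positive")
    if extension < 0:
        raise ValueError("extension must be non-negative")
    prefac = scale.kBT / persistence

    def ms(z: float) -> float:
        return prefac * (0.25 / (1.0 - z) ** 2 - 0.25 + z)

    if stretch_modulus is None:
        z = extension / contour
        if z >= 1.0:
            raise ValueError("extension must be below the contour length (inextensible WLC)")
        return ms(z)

    S = stretch_modulus

    def imbalance(F: float) -> float:
        z = extension / contour - F / S
        if z >= 1.0:
            z = 1.0 - 1e-12
        return ms(max(z, 0.0)) - F

    if extension == 0.0:
        return 0.0
    hi = 10.0
    while imbalance(hi) > 0 and hi < 1e7:
        hi *= 10.0
    return brentq(imbalance, 0.0, hi, xtol=1e-12, rtol=1e-12)


def wlc_relative_extension(force, persistence: float,
                           scale: ThermalScale = DEFAULT_SCALE):
    """Relative extension z = x/L of an inextensible Marko-Siggia WLC.

    Vectorized Newton solve of the monotone interpolation formula; accurate
    to ~1e-12 in z for forces > 0.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    g = f * persistence / scale.kBT   # dimensionless force
    # initial guess: low-force linear response / high-force asymptote
    with np.errstate(divide="ignore"):
        z = np.where(g < 1.0, 2.0 * g / 3.0, 1.0 - 0.5 / np.sqrt(np.maximum(g, 1e-300)))
    z = np.clip(z, 0.0, 1.0 - 1e-9)
    for _ in range(60):
        one_m = 1.0 - z
        h = 0.25 / one_m**2 - 0.25 + z - g
        dh = 0.5 / one_m**3 + 1.0
        step = h / dh
        z = np.clip(z - step, 0.0, 1.0 - 1e-12)
        if np.all(np.abs(step) < 1e-13):
            break
    return z if z.ndim else float(z)


def wlc_extension(
    force: float,
    contour: float,
    persistence: float,
    scale: ThermalScale = DEFAULT_SCALE,
    stretch_modulus: float | None = None,
) -> float:
    """Extension (nm) of the tether at a given force and contour length."""
    z = wlc_relative_extension(force, persistence, scale)
    if stretch_modulus is not None:
        z = z + force / stretch_modulus
    return float(z * contour)


# --------------------------------------------------------------------------
# kinetic engine
# --------------------------------------------------------------------------

# cycle states
_APO, _ADP, _PAUSE, _DOCKED, _TIGHT, _LOW, _REST = range(7)


def _kL(cfg: CycleConfig, F: float, kBT: float) -> float:
    return cfg.kL0 * (1.0 + cfg.beta * np.exp(-F * cfg.dxL / kBT))


def _kH(cfg: CycleConfig, F: float, kBT: float) -> float:
    return cfg.kH0 * np.exp(-F * cfg.dxH / kBT)


def _slip_hazard(cfg: CycleConfig, F: float, kBT: float, gripped: bool) -> float:
    h = cfg.slip_hazard0 * np.exp(F * cfg.slip_dx / kBT)
    return h * cfg.slip_suppression if gripped else h


class _CycleEngine:
    """Exact stochastic simulation of the subunit cycle at frozen force.

    Force is re-evaluated whenever the contour changes (step or slip) or,
    for an externally prescribed trajectory, at every transition.
    """

    def __init__(self, cfg: CycleConfig, scale: ThermalScale, rng: np.random.Generator):
        self.cfg = cfg
        self.kBT = scale.kBT
        self.rng = rng
        self.state = _APO
        self.log = EventLog()
        self._pause_start: float | None = None
        self._pause_force = 0.0

    def transitions(self, F: float) -> list[tuple[float, str]]:
        """(rate, label) pairs leaving the current state at force F."""
        cfg, kBT = self.cfg, self.kBT
        out: list[tuple[float, str]] = []
        if self.state == _APO:
            out.append((cfg.alpha * cfg.atp, "dock"))
            if cfg.adp > 0:
                out.append((cfg.adp_binding * cfg.adp, "adp_on"))
            if cfg.pause_entry > 0:
                out.append((cfg.pause_entry, "pause_on"))
            h = _slip_hazard(cfg, F, kBT, gripped=False)
            if h > 0:
                out.append((h, "slip"))
        elif self.state == _ADP:
            out.append((cfg.adp_binding * cfg.adp_kd, "adp_off"))
            h = _slip_hazard(cfg, F, kBT, gripped=False)
            if h > 0:
                out.append((h, "slip"))
        elif self.state == _PAUSE:
            out.append((cfg.pause_exit_rate * cfg.atp, "pause_off"))
            h = _slip_hazard(cfg, F, kBT, gripped=True)
            if h > 0:
                out.append((h, "slip"))
        elif self.state == _DOCKED:
            out.append((cfg.tight_binding, "tighten"))
            if cfg.k_unbind > 0:
                out.append((cfg.k_unbind, "undock"))
            h = _slip_hazard(cfg, F, kBT, gripped=True)
            if h > 0:
                out.append((h, "slip"))
        elif self.state == _TIGHT:
            out.append((_kL(cfg, F, kBT), "low_block"))
        elif self.state == _LOW:
            out.append((cfg.k0_rest, "rest"))
        elif self.state == _REST:
            out.append((_kH(cfg, F, kBT), "stroke"))
        if not out:
            raise ConfigurationError(f"state {self.state} has zero total exit rate")
        return out

    def advance(self, t: float, F: float) -> tuple[float, str]:
        """Draw the next dwell and transition; returns (dwell, outcome).

        ``outcome`` is "step", "slip" or "none" (internal transition).
        """
        trans = self.transitions(F)
        rates = np.array([r for r, _ in trans])
        total = rates.sum()
        dwell = self.rng.exponential(1.0 / total)
        label = trans[self.rng.choice(len(trans), p=rates / total)][1]
        t_next = t + dwell

        if label == "dock":
            self.state = _DOCKED
        elif label == "adp_on":
            self.state = _ADP
        elif label == "adp_off":
            self.state = _APO
        elif label == "pause_on":
            self.state = _PAUSE
            self._pause_start, self._pause_force = t_next, F
        elif label == "pause_off":
            self.state = _APO
            assert self._pause_start is not None
            self.log.pauses.append(
                (self._pause_start, t_next - self._pause_start, self._pause_force)
            )
            self._pause_start = None
        elif label == "undock":
            self.state = _APO
        elif label == "tighten":
            self.state = _TIGHT
        elif label == "low_block":
            self.state = _LOW
        elif label == "rest":
            self.state = _REST
        elif label == "stroke":
            self.state = _APO
            return dwell, "step"
        elif label == "slip":
            if self.state == _PAUSE and self._pause_start is not None:
                self.log.pauses.append(
                    (self._pause_start, t_next - self._pause_start, self._pause_force)
                )
                self._pause_start = None
            self.state = _APO
            return dwell, "slip"
        return dwell, "none"

    def close(self, t_end: float) -> None:
        """Close an open pause at the end of the simulation window."""
        if self._pause_start is not None:
            self.log.pauses.append(
                (self._pause_start, t_end - self._pause_start, self._pause_force)
            )
            self._pause_start = None


def _check_stroke_energy(cfg: CycleConfig, force: float) -> None:
    work = force * cfg.step_size * BP_RISE_NM
    if work > cfg.energy_budget:
        warnings.warn(
            f"power-stroke work {work:.1f} pN·nm at {force:.1f} pN exceeds the "
            f"energy budget of {cfg.energy_budget:.0f} pN·nm per ATP; "
            "configuration rejected",
            stacklevel=3,
        )
        raise ConfigurationError("configuration violates the per-ATP energy budget")


def simulate_cycle_dwells(
    config: CycleConfig,
    force_trajectory: Callable[[float], float],
    duration: float,
    scale: ThermalScale = DEFAULT_SCALE,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, EventLog]:
    """Simulate the subunit cycle against a prescribed force trajectory.

    Force is frozen within each dwell and re-evaluated at every transition.
    Returns the completed power-stroke times and the ground-truth event log
    (each stroke advances the contour by ``step_size`` bp; slips are logged
    but do not alter the prescribed force).
    """
    cfg = config.resolved()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    engine = _CycleEngine(cfg, scale, rng)
    t = 0.0
    step_times: list[float] = []
    while True:
        F = float(force_trajectory(t))
        dwell, outcome = engine.advance(t, F)
        t += dwell
        if t >= duration:
            break
        if outcome == "step":
            _check_stroke_energy(cfg, F)
            step_times.append(t)
            engine.log.steps.append((t, cfg.step_size))
        elif outcome == "slip":
            released = float(rng.exponential(cfg.slip_mean_bp))
            engine.log.slips.append((t, released, F))
    engine.close(min(t, duration))
    return np.asarray(step_times), engine.log


# --------------------------------------------------------------------------
# trap coupling and trace rendering
# --------------------------------------------------------------------------

class _TrapModel:
    """Force/extension from contour length for either operating mode."""

    def __init__(self, tether: TetherTrapConfig, scale: ThermalScale):
        self.tether = tether
        self.scale = scale
        self._trap_center: float | None = None
        if tether.mode == "passive":
            L0_nm = tether.contour_length0 * BP_RISE_NM
            x0 = wlc_extension(
                tether.initial_force, L0_nm, tether.persistence_length,
                scale, tether.stretch_modulus,
            )
            self._trap_center = x0 + tether.initial_force / tether.trap_stiffness

    def solve(self, contour_bp: float) -> tuple[float, float]:
        """Return (force pN, extension nm) at the given contour length."""
        tether = self.tether
        L_nm = contour_bp * BP_RISE_NM
        if tether.mode == "constant_force":
            F = float(tether.setpoint_force)
            x = wlc_extension(F, L_nm, tether.persistence_length, self.scale,
                              tether.stretch_modulus)
            return F, x
        # passive: WLC tension balances the trap restoring force
        c = self._trap_center
        assert c is not None
        kappa = tether.trap_stiffness

        def imbalance(x: float) -> float:
            return wlc_force(x, L_nm, tether.persistence_length, self.scale,
                             tether.stretch_modulus) - kappa * (c - x)

        hi = min(L_nm * (1.0 - 1e-9), c)
        if imbalance(hi) < 0:
            raise RuntimeError(
                "force balance unsolvable: trap cannot restrain the tether "
                f"(contour {contour_bp:.0f} bp, trap center {c:.1f} nm)"
            )
        x = brentq(imbalance, 0.0, hi, xtol=1e-9, rtol=1e-12)
        return kappa * (c - x), x


def simulate_trace(
    config: CycleConfig,
    tether: TetherTrapConfig,
    duration: float,
    scale: ThermalScale = DEFAULT_SCALE,
    rng: np.random.Generator | None = None,
) -> tuple[Trace, EventLog]:
    """Coupled cycle + trap simulation producing a sampled trace.

    The kinetic engine runs with the force frozen within each dwell; the
    force is re-solved from the trap/WLC balance whenever the contour
    changes (power stroke or slip). The returned trace carries the noisy
    observed extension and the noise-free contour channel.
    """
    cfg = config.resolved()
    if tether.mode == "constant_force":
        _check_stroke_energy(cfg, float(tether.setpoint_force))
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    engine = _CycleEngine(cfg, scale, rng)
    trap = _TrapModel(tether, scale)

    contour = tether.contour_length0
    F, x = trap.solve(contour)
    t = 0.0
    # piecewise-constant path of (time, contour, force, extension)
    bp_times = [0.0]
    bp_contour = [contour]
    bp_force = [F]
    bp_ext = [x]

    while t < duration and contour > cfg.step_size:
        dwell, outcome = engine.advance(t, F)
        t += dwell
        if t >= duration:
            break
        if outcome == "step":
            _check_stroke_energy(cfg, F)
            contour -= cfg.step_size
            engine.log.steps.append((t, cfg.step_size))
        elif outcome == "slip":
            released = float(rng.exponential(cfg.slip_mean_bp))
            released = min(released, tether.contour_length0 - contour)
            engine.log.slips.append((t, released, F))
            contour += released
        else:
            continue
        F, x = trap.solve(contour)
        bp_times.append(t)
        bp_contour.append(contour)
        bp_force.append(F)
        bp_ext.append(x)
    t_end = min(t, duration)
    engine.close(t_end)

    path = pd.DataFrame(
        {"time_s": bp_times, "contour_bp": bp_contour,
         "force_pN": bp_force, "extension_nm": bp_ext}
    )
    trace = render_trace(path, tether, duration=t_end, rng=rng,
                         metadata={"cycle": cfg.to_dict(), "tether": tether.to_dict()})
    return trace, engine.log


def render_trace(
    path: pd.DataFrame,
    tether: TetherTrapConfig,
    duration: float,
    rng: np.random.Generator | None = None,
    metadata: dict | None = None,
) -> Trace:
    """Sample a piecewise-constant state path onto the acquisition grid.

    ``path`` must hold columns time_s, contour_bp, force_pN, extension_nm at
    the event breakpoints (force already solved from the trap balance).
    Gaussian measurement noise is added to the extension channel only.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n = max(int(np.floor(duration * tether.sample_rate)), 1)
    times = np.arange(n) / tether.sample_rate
    idx = np.searchsorted(path["time_s"].to_numpy(), times, side="right") - 1
    idx = np.clip(idx, 0, len(path) - 1)
    extension = path["extension_nm"].to_numpy()[idx]
    if tether.noise_sd > 0:
        extension = extension + rng.normal(0.0, tether.noise_sd, size=n)
    return Trace(
        time=times,
        extension=extension,
        force=path["force_pN"].to_numpy()[idx],
        contour_length=path["contour_bp"].to_numpy()[idx],
        metadata=metadata or {},
    )


# --------------------------------------------------------------------------
# experiment corpus
# --------------------------------------------------------------------------

def generate_experiment(
    design: Iterable[dict],
    config: CycleConfig,
    tether: TetherTrapConfig,
    n_traces: int,
    duration: float,
    seed: int,
    scale: ThermalScale = DEFAULT_SCALE,
) -> tuple[list[tuple[Trace, EventLog]], pd.DataFrame]:
    """Simulate a grid of conditions with per-trace child seeds.

    ``design`` is an iterable of condition overrides: any of ``atp``,
    ``adp``, ``pi`` (CycleConfig fields, μM) and ``mode`` /
    ``setpoint_force`` / ``initial_force`` (TetherTrapConfig fields). The
    corpus is reproducible given ``seed``; child generators are spawned
    deterministically from one root sequence.
    """
    design = list(design)
    corpus: list[tuple[Trace, EventLog]] = []
    rows = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(design) * n_traces)
    k = 0
    for cell_id, cell in enumerate(design):
        cyc = replace(config, **{f: cell[f] for f in ("atp", "adp", "pi") if f in cell})
        tet_updates = {
            f: cell[f]
            for f in ("mode", "setpoint_force", "initial_force")
            if f in cell
        }
        if tet_updates.get("mode") == "passive":
            tet_updates.setdefault("setpoint_force", None)
        tet = replace(tether, **tet_updates) if tet_updates else tether
        for rep in range(n_traces):
            rng = np.random.default_rng(children[k])
            trace, events = simulate_trace(cyc, tet, duration, scale, rng)
            trace.metadata["cell"] = dict(cell)
            trace.metadata["replicate"] = rep
            corpus.append((trace, events))
            rows.append(
                {"trace_index": k, "cell_id": cell_id, "replicate": rep,
                 **{f"cond_{k2}": v for k2, v in cell.items()}}
            )
            k += 1
    manifest = pd.DataFrame(rows)
    return corpus, manifest
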