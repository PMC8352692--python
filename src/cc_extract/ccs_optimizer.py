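"""Cuckoo-search threshold optimization with a chaotic (Ikeda-map) step driver.

The search maximizes a thresholding criterion over integer triples
``1 <= t1 < t2 < t3 <= L-2``.  A population of nests holds candidate triples;
each generation every nest proposes a move toward the incumbent best scaled by
a step factor, a greedy rule replaces a randomly chosen nest when the proposal
scores higher, and the worst ``ceil(pa * population)`` nests are abandoned and
re-randomized.  The incumbent best is elitist: it can only improve.

Step drivers
------------
* **CCS** (chaotic cuckoo search): step factors come from the orbit of the
  Ikeda map.  The default driver iterates the canonical two-dimensional Ikeda
  map and uses its x-coordinate, whose chaotic orbit (dissipation ``u=0.9``)
  roams roughly [-0.6, 1.8] and therefore yields both interpolating and
  overshooting moves relative to the incumbent best.  A one-dimensional
  reduction ``IM = R * exp(phi - delta / (1 + c^2))`` (``R=0.75, phi=0.1,
  delta=7``) is also provided (:func:`ikeda_next`, ``driver="printed"``); that
  reduction contracts onto a fixed point near ``7.565e-4`` after a single
  iteration, so as a step driver it freezes the search — it is retained for
  fidelity experiments only (see docs/methods.md).
* **TCS** (traditional cuckoo search): heavy-tailed Levy-flight step factors
  drawn with Mantegna's algorithm (:func:`levy_step`).

Defaults follow the study conditions: population 30, three-dimensional search
space, 1500 generations, ``alpha = 1``, abandonment fraction ``pa = 0.25``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .threshold_objectives import (
    Histogram,
    ObjectiveKind,
    _Prefix,
    _score_fn,
    exhaustive_best,
    make_objective,
)

__all__ = [
    "ChaoticParams",
    "CSConfig",
    "OptTrace",
    "ikeda_next",
    "levy_step",
    "cs_optimize",
    "optimize_thresholds",
]


@dataclass(frozen=True)
class ChaoticParams:
    """Constants of the chaotic step driver.

    ``R``, ``phi``, ``delta`` parameterize the one-dimensional reduction used
    by :func:`ikeda_next`; ``grouping`` selects whether the iteration index
    ``Z`` multiplies the exponent.  ``driver`` picks the sequence feeding the
    search: ``"ikeda2d"`` (default, chaotic) or ``"printed"`` (the 1-D
    reduction, which collapses to its fixed point).  ``u`` is the dissipation
    parameter of the two-dimensional map.
    """

    R: float = 0.75
    phi: float = 0.1
    delta: float = 7.0
    grouping: str = "without_Z"
    driver: str = "ikeda2d"
    u: float = 0.9

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.grouping not in ("without_Z", "with_Z"):
            raise ValueError("grouping must be 'without_Z' or 'with_Z'")
        if self.driver not in ("ikeda2d", "printed"):
            raise ValueError("driver must be 'ikeda2d' or 'printed'")


_CLAMP_LO, _CLAMP_HI = 1e-12, 1e3


def ikeda_next(c, Z: int = 1, params: ChaoticParams | None = None):
    """One step of the 1-D Ikeda-style map ``R * exp(phi - delta/(1+c^2))``.

    With ``grouping="with_Z"`` the whole exponent is multiplied by the
    iteration index ``Z``.  The result is clamped to ``[1e-12, 1e3]`` to keep
    the ``with_Z`` reading finite.  Deterministic; accepts scalars or arrays.
    """
    p = params or ChaoticParams()
    c = np.asarray(c, dtype=float)
    expo = p.phi - p.delta / (1.0 + c * c)
    if p.grouping == "with_Z":
        expo = Z * expo
    out = np.clip(p.R * np.exp(np.clip(expo, -745.0, 709.0)), _CLAMP_LO, _CLAMP_HI)
    return float(out) if out.ndim == 0 else out


def levy_step(beta: float = 1.5, rng: np.random.Generator | None = None, size=None):
    """Heavy-tailed Levy-flight step (Mantegna's algorithm), stability ``beta``."""
    if not 0 < beta <= 2:
        raise ValueError("beta must lie in (0, 2]")
    rng = rng if rng is not None else np.random.default_rng()
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma_u = (num / den) ** (1 / beta)
    u = rng.normal(0.0, sigma_u, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1 / beta)


@dataclass
class CSConfig:
    """Search configuration (defaults are the study conditions)."""

    population: int = 30
    dim: int = 3
    max_iter: int = 1500
    alpha: float = 1.0
    pa: float = 0.25
    bounds: tuple = ((1, 254), (1, 254), (1, 254))
    seed: int = 0
    step_mode: str = "guided"
    patience: int | None = None  # None: fixed-length run

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must exceed 1")
        if not 0 <= self.pa <= 1:
            raise ValueError("pa must lie in [0, 1]")
        if len(self.bounds) != self.dim:
            raise ValueError("bounds length must match dim")
        for lo, hi in self.bounds:
            if hi - lo + 1 < self.dim:
                raise ValueError(
                    f"bound ({lo}, {hi}) too narrow for {self.dim} "
                    "strictly increasing integer coordinates"
                )
        if self.step_mode not in ("guided", "literal"):
            raise ValueError("step_mode must be 'guided' or 'literal'")


@dataclass
class OptTrace:
    """Convergence record: elitist best-so-far score per generation."""

    best_score_per_iter: list = field(default_factory=list)
    best_T: tuple = ()
    evaluations: int = 0
    converged_at: int = 0


class _Ikeda2D:
    """Per-agent orbits of the canonical 2-D Ikeda map; emits x-coordinates."""

    def __init__(self, n: int, rng: np.random.Generator, u: float) -> None:
        self.u = u
        self.x = rng.uniform(-0.5, 1.5, size=n)
        self.y = rng.uniform(-1.5, 1.0, size=n)

    def draw_all(self, k: int) -> np.ndarray:
        out = np.empty((self.x.size, k))
        x, y, u = self.x, self.y, self.u
        for j in range(k):
            t = 0.4 - 6.0 / (1.0 + x * x + y * y)
            ct, st = np.cos(t), np.sin(t)
            x, y = 1.0 + u * (x * ct - y * st), u * (x * st + y * ct)
            out[:, j] = x
        self.x, self.y = x, y
        return out

    def reset(self, idx, rng: np.random.Generator) -> None:
        self.x[idx] = rng.uniform(-0.5, 1.5, size=len(idx))
        self.y[idx] = rng.uniform(-1.5, 1.0, size=len(idx))


class _Printed1D:
    """The 1-D reduction as a step driver (collapses to its fixed point)."""

    def __init__(self, n: int, rng: np.random.Generator, params: ChaoticParams) -> None:
        self.params = params
        self.c = rng.uniform(0.0, 1.0, size=n)
        self.z = 1

    def draw_all(self, k: int) -> np.ndarray:
        out = np.empty((self.c.size, k))
        for j in range(k):
            self.c = ikeda_next(self.c, Z=self.z, params=self.params)
            self.z += 1
            out[:, j] = self.c
        return out

    def reset(self, idx, rng: np.random.Generator) -> None:
        self.c[idx] = rng.uniform(0.0, 1.0, size=len(idx))


def _repair_batch(props: np.ndarray, lows: np.ndarray, highs: np.ndarray) -> np.ndarray:
    """Round, clamp, sort rows ascending, separate ties by minimal unit shifts."""
    t = np.sort(np.rint(np.clip(props, lows, highs)), axis=1).astype(np.int64)
    d = t.shape[1]
    for k in range(1, d):  # push duplicates up
        t[:, k] = np.maximum(t[:, k], t[:, k - 1] + 1)
    t[:, d - 1] = np.minimum(t[:, d - 1], int(highs[d - 1]))
    for k in range(d - 2, -1, -1):  # push back down if shifted past the bound
        t[:, k] = np.minimum(t[:, k], t[:, k + 1] - 1)
    if np.any(t < lows.astype(np.int64)):
        raise ValueError("bounds too tight to repair a strictly increasing vector")
    return t


def _repair(x, lows, highs) -> tuple:
    """Single-vector repair: round, clamp, sort, de-duplicate by unit shifts."""
    lows = np.asarray(lows, dtype=float)
    highs = np.asarray(highs, dtype=float)
    t = _repair_batch(np.asarray(x, dtype=float)[None, :], lows, highs)[0]
    return tuple(int(v) for v in t)


def cs_optimize(objective, cfg: CSConfig, chaos: ChaoticParams | None = None,
                objective_batch=None):
    """Maximize ``objective`` over sorted integer vectors within ``cfg.bounds``.

    ``objective`` maps one integer tuple to a score; ``objective_batch``, if
    given, maps an ``(N, dim)`` integer array to ``(N,)`` scores and is used
    to evaluate whole generations at once.  ``chaos`` selects the chaotic
    driver (CCS); ``chaos=None`` runs the Levy-flight baseline (TCS).
    Returns ``(best_T, best_score, trace)``; identical configuration and seed
    reproduce the run exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    lows = np.array([b[0] for b in cfg.bounds], dtype=float)
    highs = np.array([b[1] for b in cfg.bounds], dtype=float)
    P, d = cfg.population, cfg.dim
    if objective_batch is None:
        def objective_batch(Ts):
            return np.array([objective(tuple(row)) for row in Ts])

    pop = np.sort(rng.uniform(lows, highs, size=(P, d)), axis=1)
    if chaos is not None:
        driver = (
            _Ikeda2D(P, rng, chaos.u)
            if chaos.driver == "ikeda2d"
            else _Printed1D(P, rng, chaos)
        )
    else:
        driver = None

    trace = OptTrace()
    scores = objective_batch(_repair_batch(pop, lows, highs)).astype(float)
    trace.evaluations = P
    best_i = int(np.argmax(scores))
    best_T = _repair(pop[best_i], lows, highs)
    best_score = float(scores[best_i])
    best_pos = pop[best_i].copy()
    trace.converged_at = 0

    n_abandon = math.ceil(cfg.pa * P)
    for it in range(1, cfg.max_iter + 1):
        if driver is not None:
            S = driver.draw_all(d)
        else:
            S = levy_step(1.5, rng, size=(P, d))
        if cfg.step_mode == "guided":
            props = pop + cfg.alpha * S * (best_pos - pop)
        else:  # literal positive drift, kept for fidelity experiments
            props = pop + cfg.alpha * S
        props = np.clip(props, lows, highs)
        Ts = _repair_batch(props, lows, highs)
        # a proposal that rounds back onto its own nest explores nothing;
        # nudge one coordinate by a unit step so collapsed nests keep
        # probing the integer neighborhood of the incumbent
        cur = _repair_batch(pop, lows, highs)
        stuck = np.flatnonzero(np.all(Ts == cur, axis=1))
        if stuck.size:
            ks = rng.integers(d, size=stuck.size)
            signs = rng.integers(2, size=stuck.size) * 2 - 1
            props[stuck, ks] = np.clip(
                props[stuck, ks] + signs, lows[ks], highs[ks]
            )
            Ts = _repair_batch(props, lows, highs)
        scs = objective_batch(Ts).astype(float)
        trace.evaluations += P

        js = rng.integers(P, size=P)
        for i in range(P):
            if scs[i] > scores[js[i]]:
                pop[js[i]] = props[i]
                scores[js[i]] = scs[i]
        for k in range(P):
            T_k = tuple(int(v) for v in Ts[k])
            # ties break toward the lexicographically smaller triple (the
            # enumeration oracle's convention); tie drift also walks score
            # plateaus that strict improvement cannot leave
            if scs[k] > best_score or (scs[k] == best_score and T_k < best_T):
                if scs[k] > best_score:
                    trace.converged_at = it
                best_score = float(scs[k])
                best_T = T_k
                best_pos = props[k].copy()

        # abandon the worst nests (the current best nest is protected)
        order = np.argsort(scores, kind="stable")
        protected = int(np.argmax(scores))
        dropped = np.array([k for k in order if k != protected][:n_abandon], dtype=int)
        if dropped.size:
            fresh = np.sort(rng.uniform(lows, highs, size=(dropped.size, d)), axis=1)
            pop[dropped] = fresh
            Tf = _repair_batch(fresh, lows, highs)
            scf = objective_batch(Tf).astype(float)
            scores[dropped] = scf
            trace.evaluations += dropped.size
            if driver is not None:
                driver.reset(dropped, rng)
            for k in range(len(dropped)):
                T_k = tuple(int(v) for v in Tf[k])
                if scf[k] > best_score or (scf[k] == best_score and T_k < best_T):
                    if scf[k] > best_score:
                        trace.converged_at = it
                    best_score = float(scf[k])
                    best_T = T_k
                    best_pos = fresh[k].copy()

        trace.best_score_per_iter.append(best_score)
        if cfg.patience is not None and it - trace.converged_at >= cfg.patience:
            break

    trace.best_T = best_T
    return best_T, float(best_score), trace


def _make_batch_objective(h: Histogram, kind: ObjectiveKind):
    pref = _Prefix.build(h)
    fn = _score_fn(pref, kind)

    def batch(Ts: np.ndarray) -> np.ndarray:
        Ts = np.asarray(Ts, dtype=np.int64)
        return np.asarray(fn(Ts[:, 0], Ts[:, 1], Ts[:, 2]), dtype=float)

    return batch


def optimize_thresholds(
    h: Histogram,
    kind: ObjectiveKind,
    cfg: CSConfig | None = None,
    method: str = "ccs",
    chaos: ChaoticParams | None = None,
):
    """Find the maximizing threshold triple for a histogram.

    ``method`` is one of ``"ccs"`` (chaotic cuckoo search), ``"tcs"``
    (Levy-flight baseline) or ``"exhaustive"`` (enumeration oracle).
    Returns ``(T, score, trace)``.
    """
    cfg = cfg or CSConfig()
    L = h.nbins
    cfg = replace(cfg, bounds=tuple((1, L - 2) for _ in range(cfg.dim)))
    if method == "exhaustive":
        T, score = exhaustive_best(h, kind)
        n = (L - 2) * (L - 3) * (L - 4) // 6
        return T, score, OptTrace([score], T, n, 0)
    objective = make_objective(h, kind)
    batch = _make_batch_objective(h, kind)
    if method == "ccs":
        return cs_optimize(objective, cfg, chaos=chaos or ChaoticParams(),
                           objective_batch=batch)
    if method == "tcs":
        return cs_optimize(objective, cfg, chaos=None, objective_batch=batch)
    raise ValueError(f"unknown method {method!r}")
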