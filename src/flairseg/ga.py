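"""Maximising total fuzzy entropy over the six membership knots.

The search space is the set of ordered six-tuples ``a1 <= ... <= a6`` on the
256 gray levels.  Two optimisers are provided:

* :func:`run_ga` — a classical simple genetic algorithm (48-bit chromosomes
  holding six bytes, roulette-wheel selection, single-point crossover,
  per-bit mutation, elitism of one).  Unordered chromosomes are repaired by
  sorting the six decoded bytes, so every chromosome is legal.
* :func:`exhaustive_search` — the exact global optimum on a regular
  parameter grid, used as an independent yardstick for the GA.

The exhaustive search exploits an exact decomposition of the objective: the
dark spline is supported on ``k <= a3`` and the bright spline on ``k > a4``
with ``a3 <= a4``, so the medium-class entropy splits into a per-dark-triple
term, a per-bright-triple term and an O(1) coupling through the medium class
probability.  A Pareto reduction (the coupling is monotone in each
per-triple summary) then shrinks both triple tables before the pairwise
maximisation, keeping the full grid search exact but fast.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fuzzy import Histogram, FuzzyParams, _entropy_batch, _z_curve, _LEVELS

N_BITS = 48
_BYTE_WEIGHTS = 2 ** np.arange(7, -1, -1)

__all__ = ["GAConfig", "GAResult", "decode_chromosome", "run_ga", "exhaustive_search"]


@dataclass(frozen=True)
class GAConfig:
    """Settings of the simple genetic algorithm.

    Defaults follow the classical SGA configuration for this problem:
    population 300, crossover probability 0.5, per-bit mutation probability
    0.01; fitness is the total fuzzy entropy.  The generation budget of 300
    is split by ``restart_every`` into five independent epochs, which makes
    the fit robust on near-degenerate (spiky) histograms where a single run
    of the SGA can settle in a secondary entropy basin.
    """

    population_size: int = 300
    p_crossover: float = 0.5
    p_mutation: float = 0.01
    max_generations: int = 300
    seed: int = 0
    restart_every: int | None = 60
    polish: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0 <= self.p_crossover <= 1 and 0 <= self.p_mutation <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.restart_every is not None and self.restart_every < 1:
            raise ValueError("restart_every must be >= 1 or None")


@dataclass(frozen=True)
class GAResult:
    params: FuzzyParams
    entropy: float
    trace: np.ndarray = field(repr=False)


def decode_chromosome(bits) -> FuzzyParams:
    """Decode 48 binary genes into ordered membership knots.

    Each byte is read as a reflected Gray code (so a single bit flip moves
    a knot by a small amount instead of jumping across the intensity scale)
    and the six raw values are sorted ascending.  Decoding is total: every
    chromosome maps to a legal parameter vector.
    """
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.shape != (N_BITS,) or np.any(bits > 1):
        raise ValueError("chromosome must be 48 binary genes")
    raw = np.bitwise_xor.accumulate(bits.reshape(6, 8), axis=1) @ _BYTE_WEIGHTS
    return FuzzyParams(tuple(int(v) for v in np.sort(raw)))


def _decode_population(pop: np.ndarray) -> np.ndarray:
    binary = np.bitwise_xor.accumulate(pop.reshape(pop.shape[0], 6, 8), axis=2)
    return np.sort(binary @ _BYTE_WEIGHTS, axis=1)


def _polish(p: np.ndarray, params: tuple, value: float) -> tuple[tuple, float]:
    """Deterministic coordinate-descent refinement of the six knots.

    Each knot in turn is tried at every integer gray level (the candidate
    vector is re-sorted, so a knot may migrate past its neighbours); sweeps
    repeat until no knot moves.  This sharpens the GA solution to a
    coordinatewise optimum of the entropy surface.
    """
    a = list(params)
    for _ in range(32):
        moved = False
        for i in range(6):
            cand = np.tile(a, (256, 1)).astype(float)
            cand[:, i] = np.arange(256)
            cand.sort(axis=1)
            vals = _entropy_batch(p, cand)
            j = int(np.argmax(vals))
            if vals[j] > value + 1e-12:
                value = float(vals[j])
                a = [int(v) for v in sorted(a[:i] + [j] + a[i + 1:])]
                moved = True
        if not moved:
            break
    return tuple(int(v) for v in a), value


def run_ga(hist: Histogram, cfg: GAConfig | None = None) -> GAResult:
    """Maximise total fuzzy entropy with the simple genetic algorithm.

    Returns the best-ever parameter vector, its entropy, and the
    per-generation best-so-far fitness trace (non-decreasing, since the best
    individual is preserved by elitism).  Identical seed, configuration and
    histogram give bit-identical results.

    Two convergence aids supplement the classical operators.  With
    ``restart_every`` the run is split into independent epochs: after that
    many generations the population is re-randomised (a cataclysmic
    restart) and each epoch evolves its own elite — reinjecting the global
    best would immediately re-dominate the roulette and defeat the restart.
    With ``polish`` each epoch's best knots are refined by deterministic
    coordinate descent before entering the global best.
    """
    if cfg is None:
        cfg = GAConfig()
    rng = np.random.default_rng(cfg.seed)
    p = hist.p
    n = cfg.population_size

    pop = rng.integers(0, 2, size=(n, N_BITS), dtype=np.uint8)
    cache: dict[tuple, float] = {}
    best_f = -np.inf
    best_params: tuple | None = None
    trace = np.empty(cfg.max_generations)

    def evaluate(pop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        decoded = _decode_population(pop)
        fit = np.empty(n)
        missing_rows = []
        missing_keys = []
        for i in range(n):
            key = tuple(decoded[i])
            val = cache.get(key)
            if val is None and key not in missing_keys:
                missing_keys.append(key)
                missing_rows.append(decoded[i])
        if missing_rows:
            vals = _entropy_batch(p, np.array(missing_rows))
            for key, val in zip(missing_keys, vals):
                cache[key] = float(val)
        for i in range(n):
            fit[i] = cache[tuple(decoded[i])]
        return fit, decoded

    def finish_epoch(epoch_f: float, epoch_params: tuple | None) -> None:
        nonlocal best_f, best_params
        if epoch_params is None:
            return
        if cfg.polish:
            epoch_params, epoch_f = _polish(p, epoch_params, epoch_f)
        if epoch_f > best_f:
            best_f = epoch_f
            best_params = epoch_params

    epoch_f = -np.inf
    epoch_bits: np.ndarray | None = None
    epoch_params: tuple | None = None
    gen_in_epoch = 0
    for gen in range(cfg.max_generations):
        fit, decoded = evaluate(pop)
        i_best = int(np.argmax(fit))
        if fit[i_best] > epoch_f:
            epoch_f = float(fit[i_best])
            epoch_bits = pop[i_best].copy()
            epoch_params = tuple(int(v) for v in decoded[i_best])
        trace[gen] = max(best_f, epoch_f)
        gen_in_epoch += 1

        if gen == cfg.max_generations - 1:
            break

        if cfg.restart_every is not None and gen_in_epoch >= cfg.restart_every:
            finish_epoch(epoch_f, epoch_params)
            pop = rng.integers(0, 2, size=(n, N_BITS), dtype=np.uint8)
            epoch_f = -np.inf
            epoch_bits = None
            epoch_params = None
            gen_in_epoch = 0
            continue

        # roulette-wheel selection with fitness windowing: selection weight
        # proportional to the margin over the worst individual, which keeps
        # useful selection pressure once the population has converged to a
        # narrow fitness band (raw entropies differ by a few percent only)
        weights = fit - fit.min()
        total = weights.sum()
        probs = weights / total if total > 0 else np.full(n, 1.0 / n)
        probs = probs / probs.sum()
        parents = pop[rng.choice(n, size=n, p=probs)].copy()

        # single-point crossover on consecutive pairs
        for j in range(0, n - 1, 2):
            if rng.random() < cfg.p_crossover:
                pt = int(rng.integers(1, N_BITS))
                tmp = parents[j, pt:].copy()
                parents[j, pt:] = parents[j + 1, pt:]
                parents[j + 1, pt:] = tmp

        # per-bit mutation, then elitism (the best of the current epoch)
        flips = rng.random(parents.shape) < cfg.p_mutation
        parents ^= flips.astype(np.uint8)
        parents[0] = epoch_bits
        pop = parents

    finish_epoch(epoch_f, epoch_params)
    trace[-1] = best_f
    if best_f <= 0.0:
        warnings.warn(
            "degenerate histogram: total fuzzy entropy is 0 for every "
            "parameter vector", stacklevel=2,
        )
    return GAResult(params=FuzzyParams(best_params), entropy=best_f, trace=trace)


def _grid_levels(grid_step: int) -> np.ndarray:
    levels = np.arange(0, 256, grid_step)
    if levels[-1] != 255:
        levels = np.append(levels, 255)
    return levels


def _xlogx(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0)), 0.0)


def _triple_summaries(p: np.ndarray, triples: np.ndarray, chunk: int = 4096):
    """Per-triple summaries (H, correction, class probability) for the dark
    spline Z(a,b,c) and the bright spline S(a,b,c) on the same triple list."""
    n = len(triples)
    out = {
        "dark": (np.empty(n), np.empty(n), np.empty(n)),
        "bright": (np.empty(n), np.empty(n), np.empty(n)),
    }
    hp = _xlogx(p)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        t = triples[lo:hi].astype(float)
        z = _z_curve(_LEVELS, t[:, 0:1], t[:, 1:2], t[:, 2:3])
        for name, mu in (("dark", z), ("bright", 1.0 - z)):
            H_arr, C_arr, P_arr = out[name]
            q = p * mu
            P = q.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                tt = q / P[:, None]
                term = np.where(q > 0, tt * np.log(tt), 0.0)
            H = -np.nansum(term, axis=1)
            H[P <= 0] = 0.0
            corr = np.where(mu > 0, _xlogx(p * (1.0 - mu)) - hp, 0.0).sum(axis=1)
            H_arr[lo:hi] = H
            C_arr[lo:hi] = corr
            P_arr[lo:hi] = P
    return out


def _pareto_front(H: np.ndarray, C: np.ndarray, P: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Indices of tuples not dominated in (H max; C, P, K min).

    The pair objective is increasing in H and decreasing in each of C, P and
    the constraint key K, so dominated tuples can never attain the maximum.
    """
    n = len(H)
    order = np.lexsort((K, P, C, -H))
    fH = np.empty(n)
    fC = np.empty(n)
    fP = np.empty(n)
    fK = np.empty(n)
    keep = np.empty(n, dtype=np.int64)
    m = 0
    for idx in order:
        if m and np.any(
            (fH[:m] >= H[idx]) & (fC[:m] <= C[idx]) & (fP[:m] <= P[idx]) & (fK[:m] <= K[idx])
        ):
            continue
        fH[m] = H[idx]
        fC[m] = C[idx]
        fP[m] = P[idx]
        fK[m] = K[idx]
        keep[m] = idx
        m += 1
    return keep[:m]


def exhaustive_search(hist: Histogram, grid_step: int = 4) -> tuple[FuzzyParams, float]:
    """Exact maximum of the total fuzzy entropy on a regular parameter grid.

    Every ordered six-tuple over the levels ``{0, grid_step, 2*grid_step,
    ..., 255}`` is considered.  The result is the global grid optimum; see
    the module docstring for how the enumeration is made tractable.
    """
    if grid_step < 1:
        raise ValueError("grid_step must be >= 1")
    levels = _grid_levels(int(grid_step))
    if len(levels) < 6:
        raise ValueError("grid too coarse: fewer than 6 levels")
    p = hist.p

    triples = np.array(
        list(itertools.combinations_with_replacement(levels, 3)), dtype=np.int64
    )
    summ = _triple_summaries(p, triples)
    Hd, Ad, Pd = summ["dark"]
    Hb, Bb, Pb = summ["bright"]
    G = float(_xlogx(p).sum())

    # constraint: dark a3 <= bright a4.  Smaller a3 / larger a4 is more
    # permissive, so both enter the dominance check with "min" sense.
    d_keep = _pareto_front(Hd, Ad, Pd, triples[:, 2].astype(float))
    b_keep = _pareto_front(Hb, Bb, Pb, -triples[:, 0].astype(float))

    bH, bB, bP = Hb[b_keep], Bb[b_keep], Pb[b_keep]
    b_a4 = triples[b_keep, 0]

    best_val = -np.inf
    best_pair = (0, 0)
    for i in d_keep:
        valid = b_a4 >= triples[i, 2]
        if not np.any(valid):
            continue
        Pm = 1.0 - Pd[i] - bP[valid]
        with np.errstate(divide="ignore", invalid="ignore"):
            Hm = np.where(
                Pm > 1e-15, np.log(np.where(Pm > 0, Pm, 1.0)) - (G + Ad[i] + bB[valid]) / Pm, 0.0
            )
        tot = Hd[i] + bH[valid] + Hm
        j = int(np.argmax(tot))
        if tot[j] > best_val:
            best_val = float(tot[j])
            best_pair = (int(i), int(b_keep[np.nonzero(valid)[0][j]]))

    dark = triples[best_pair[0]]
    bright = triples[best_pair[1]]
    params = FuzzyParams(tuple(int(v) for v in np.concatenate([dark, bright])))
    return params, best_val
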