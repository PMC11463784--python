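"""Genetic-programming symbolic regression over (temperature, precipitation).

Distills the trained oviposition network into a closed-form expression.
Candidate expressions are binary trees over the function set
{add, sub, mul, div, sig} and terminals {T, R, ephemeral constant}, stored
in prefix (depth-first) order. Division is protected (|denominator| below
1e-3 evaluates to 1) and ``sig`` is the logistic sigmoid, so every tree is
finite on finite inputs.

Raw fitness is the mean squared error against the network's outputs on a
training grid (dense at low precipitation where the surface curves most);
selection uses the raw fitness plus a parsimony penalty proportional to
node count. Reproduction is tournament selection followed by crossover,
subtree mutation, hoist mutation, point mutation, or plain copying, with an
elite individual carried over each generation.

The module also ships the fixed closed-form reference expression recovered
for the oviposition rate — a logistic S-curve in temperature whose
threshold is modulated by precipitation-temperature interaction terms —
used as the planted ground truth of the synthetic benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ExprTree", "GPConfig", "build_training_grid", "validation_grid",
    "eval_tree", "fitness", "evolve", "eval_reference",
    "validate_against_network", "REFERENCE_LOWER", "REFERENCE_UPPER",
]

ARITY = {"add": 2, "sub": 2, "mul": 2, "div": 2, "sig": 1}
FUNCTIONS = tuple(ARITY)
DIV_GUARD = 1e-3
MAX_NODES = 256  # bloat cap; oversized offspring fall back to a parent copy

# Output bounds of the reference oviposition expression (eggs/adult/day).
REFERENCE_LOWER = 4.0
REFERENCE_UPPER = 20.0


@dataclass
class ExprTree:
    """An expression in prefix order: functions by name, variables by index
    (0 = T, 1 = R), ephemeral constants as floats."""

    program: list

    def __post_init__(self):
        if _subtree_end(self.program, 0) != len(self.program):
            raise ValueError("malformed program: arity mismatch")

    def __len__(self):
        return len(self.program)

    @property
    def depth(self) -> int:
        depth, max_depth, pending = 0, 0, [1]
        for node in self.program:
            pending[-1] -= 1
            max_depth = max(max_depth, len(pending))
            if isinstance(node, str):
                pending.append(ARITY[node])
            else:
                while pending and pending[-1] == 0:
                    pending.pop()
        return max_depth

    def evaluate(self, T, R):
        return eval_tree(self, T, R)

    def to_sexpr(self) -> str:
        out, _ = _sexpr(self.program, 0)
        return out

    def to_infix(self) -> str:
        out, _ = _infix(self.program, 0)
        return out


def _sexpr(prog, i):
    node = prog[i]
    if isinstance(node, str):
        parts = []
        j = i + 1
        for _ in range(ARITY[node]):
            s, j = _sexpr(prog, j)
            parts.append(s)
        return f"({node} {' '.join(parts)})", j
    if isinstance(node, int):
        return ("T", "R")[node], i + 1
    return f"{node:.4f}", i + 1


_INFIX_OP = {"add": "+", "sub": "-", "mul": "*", "div": "/"}


def _infix(prog, i):
    node = prog[i]
    if isinstance(node, str):
        if node == "sig":
            a, j = _infix(prog, i + 1)
            return f"sig({a})", j
        a, j = _infix(prog, i + 1)
        b, j = _infix(prog, j)
        return f"({a} {_INFIX_OP[node]} {b})", j
    if isinstance(node, int):
        return ("T", "R")[node], i + 1
    return f"{node:.4f}", i + 1


def _subtree_end(prog, start: int) -> int:
    """Index one past the subtree rooted at ``start``."""
    need, i = 1, start
    while need:
        if i >= len(prog):
            raise ValueError("malformed program")
        node = prog[i]
        need += (ARITY[node] - 1) if isinstance(node, str) else -1
        i += 1
    return i


@dataclass
class GPConfig:
    """Hyperparameters of the evolutionary search.

    The reproduction probabilities, population size, generation limit,
    parsimony coefficient, stopping threshold and initial depths follow the
    full-scale distillation protocol. ``brood_size``, the per-node point-
    replacement rate and the constant-jitter scales govern engine internals
    (see :func:`evolve`); ``const_range`` is the sampling range for fresh
    ephemeral constants — evolved constants may drift outside it.
    """

    population_size: int = 6000
    generations: int = 40
    stopping_criteria: float = 0.01   # stop when best raw MSE falls below
    p_crossover: float = 0.1
    p_subtree_mutation: float = 0.1
    p_hoist_mutation: float = 0.07
    p_point_mutation: float = 0.1
    p_point_replace: float = 0.5      # per-node replacement rate inside point mutation
    parsimony_coefficient: float = 0.02
    init_depth: tuple = (2, 6)
    tournament_size: int = 20
    const_range: tuple = (-20.0, 20.0)
    brood_size: int = 32              # offspring drafted per variation event
    const_jitter_scales: tuple = (0.1, 0.5, 2.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        probs = (self.p_crossover, self.p_subtree_mutation,
                 self.p_hoist_mutation, self.p_point_mutation)
        if any(not 0 <= p <= 1 for p in probs) or sum(probs) > 1 + 1e-12:
            raise ValueError("variation probabilities must lie in [0,1] and sum to <= 1")
        if self.population_size < 2:
            raise ValueError("population must hold at least 2 individuals")
        if self.brood_size < 1:
            raise ValueError("brood_size must be at least 1")


def build_training_grid() -> np.ndarray:
    """(T, R) pairs used to interrogate the network: temperature 15-35 deg C
    at 1 deg C steps crossed with precipitation 0-30 mm at 1 mm, 31-141 mm at
    10 mm, and 150-200 mm at 5 mm steps (dense where the surface bends)."""
    T = np.arange(15.0, 36.0, 1.0)
    R = np.concatenate([np.arange(0.0, 31.0, 1.0),
                        np.arange(31.0, 150.0, 10.0),
                        np.arange(150.0, 201.0, 5.0)])
    TT, RR = np.meshgrid(T, R, indexing="ij")
    return np.column_stack([TT.ravel(), RR.ravel()])


def validation_grid() -> np.ndarray:
    """Finer held-out grid: 15-35 deg C at 0.5 deg C x 0-200 mm at 1 mm."""
    T = np.arange(15.0, 35.5, 0.5)
    R = np.arange(0.0, 201.0, 1.0)
    TT, RR = np.meshgrid(T, R, indexing="ij")
    return np.column_stack([TT.ravel(), RR.ravel()])


def eval_tree(tree, T, R):
    """Evaluate a tree (or raw program) on scalars or arrays; always finite."""
    prog = tree.program if isinstance(tree, ExprTree) else tree
    T = np.asarray(T, dtype=float)
    R = np.asarray(R, dtype=float)
    shape = np.broadcast_shapes(T.shape, R.shape)
    stack = []
    for node in reversed(prog):
        if isinstance(node, str):
            if node == "sig":
                stack.append(expit(stack.pop()))
            else:
                a, b = stack.pop(), stack.pop()
                if node == "add":
                    stack.append(a + b)
                elif node == "sub":
                    stack.append(a - b)
                elif node == "mul":
                    stack.append(_safe_clip(a * b))
                else:  # protected division
                    small = np.abs(b) < DIV_GUARD
                    stack.append(_safe_clip(np.where(small, 1.0, a / np.where(small, 1.0, b))))
        elif isinstance(node, int):
            stack.append(np.broadcast_to((T, R)[node], shape))
        else:
            stack.append(np.broadcast_to(float(node), shape))
    out = np.broadcast_to(stack[-1], shape)
    return float(out) if out.ndim == 0 else np.asarray(out)


def _safe_clip(x):
    # keep products/quotients finite so nested trees never overflow
    return np.clip(x, -1e30, 1e30)


def fitness(tree, grid: np.ndarray, targets: np.ndarray,
            parsimony: float = 0.0):
    """Raw MSE over the grid, plus optional parsimony-penalized variant."""
    targets = np.asarray(targets, dtype=float)
    if len(targets) != len(grid):
        raise ValueError("targets must align with the grid")
    pred = eval_tree(tree, grid[:, 0], grid[:, 1])
    raw = float(np.mean((pred - targets) ** 2))
    if parsimony == 0.0:
        return raw
    n = len(tree.program) if isinstance(tree, ExprTree) else len(tree)
    return raw + parsimony * n


# ---------------------------------------------------------------------------
# evolution engine


def _random_terminal(rng, const_range):
    choice = rng.integers(3)
    if choice < 2:
        return int(choice)
    return float(rng.uniform(*const_range))


def _random_program(rng, depth: int, method: str, const_range) -> list:
    """'full' places functions at every interior level; 'grow' mixes freely."""
    prog = []
    stack = [depth]
    while stack:
        d = stack.pop()
        if d > 0 and (method == "full" or rng.random() < 0.6):
            fn = FUNCTIONS[rng.integers(len(FUNCTIONS))]
            prog.append(fn)
            stack.extend([d - 1] * ARITY[fn])
        else:
            prog.append(_random_terminal(rng, const_range))
    return prog


_LEAF_WEIGHT = 0.25  # chance mass assigned to leaves when picking variation points
# depth distribution of subtree-mutation donors, biased shallow so that small
# refinable motifs are proposed often
_DONOR_DEPTHS = (2, 2, 2, 2, 3, 3, 4, 5, 6)


def _random_subtree(rng, prog):
    """Pick a subtree, weighting interior nodes above leaves (75/25)."""
    weights = np.array([1.0 - _LEAF_WEIGHT if isinstance(n, str) else _LEAF_WEIGHT
                        for n in prog])
    idx = int(rng.choice(len(prog), p=weights / weights.sum()))
    return idx, _subtree_end(prog, idx)


def _crossover(rng, parent, donor):
    i, j = _random_subtree(rng, parent)
    a, b = _random_subtree(rng, donor)
    child = parent[:i] + donor[a:b] + parent[j:]
    return child if len(child) <= MAX_NODES else list(parent)


def _subtree_mutation(rng, parent, cfg):
    depth = _DONOR_DEPTHS[rng.integers(len(_DONOR_DEPTHS))]
    method = "full" if rng.random() < 0.5 else "grow"
    replacement = _random_program(rng, depth, method, cfg.const_range)
    i, j = _random_subtree(rng, parent)
    child = parent[:i] + replacement + parent[j:]
    return child if len(child) <= MAX_NODES else list(parent)


def _hoist_mutation(rng, parent):
    i, j = _random_subtree(rng, parent)
    sub = parent[i:j]
    a, b = _random_subtree(rng, sub)
    return parent[:i] + sub[a:b] + parent[j:]


def _point_mutation(rng, parent, cfg):
    """Per-node replacement; ephemeral constants mostly take a Gaussian step.

    Jitter scales are mixed over ``const_jitter_scales`` and the walk is NOT
    clipped to ``const_range`` — the range bounds the sampling distribution
    of fresh constants, while selection alone governs where evolved
    constants settle.
    """
    prog = list(parent)
    for idx in np.flatnonzero(rng.random(len(prog)) < cfg.p_point_replace):
        node = prog[idx]
        if isinstance(node, str):
            same = [f for f in FUNCTIONS if ARITY[f] == ARITY[node]]
            prog[idx] = same[rng.integers(len(same))]
        elif isinstance(node, float) and rng.random() < 0.7:
            sd = cfg.const_jitter_scales[rng.integers(len(cfg.const_jitter_scales))]
            prog[idx] = float(node + rng.normal(0.0, sd))
        else:
            prog[idx] = _random_terminal(rng, cfg.const_range)
    return prog


def evolve(grid: np.ndarray, targets: np.ndarray, cfg: GPConfig):
    """Run the evolutionary search; returns (best ExprTree, stats per generation).

    Engine design, beyond the configured reproduction scheme (tournament
    selection, then crossover / subtree / hoist / point mutation or copy):

    * brood recombination — every variation event drafts ``brood_size``
      candidate offspring and keeps the one with the best penalized fitness,
      which makes constant walks and structural rearrangements far more
      effective at small population sizes;
    * selection pools are deduplicated by genotype, so copies produced by
      reproduction do not swamp tournaments and novel structures keep a
      selection share while they refine;
    * one elite (best-so-far raw MSE, ties toward fewer nodes) is carried
      into each generation, making best raw fitness non-increasing.

    Fully reproducible for a given config and seed.
    """
    if len(grid) == 0:
        raise ValueError("empty training data")
    targets = np.asarray(targets, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.init_depth

    population = []
    for i in range(cfg.population_size):
        depth = lo + (i % (hi - lo + 1))
        method = "full" if (i // (hi - lo + 1)) % 2 == 0 else "grow"
        population.append(_random_program(rng, depth, method, cfg.const_range))

    p_cx = cfg.p_crossover
    p_sub = p_cx + cfg.p_subtree_mutation
    p_hoist = p_sub + cfg.p_hoist_mutation
    p_point = p_hoist + cfg.p_point_mutation
    parsimony = cfg.parsimony_coefficient

    best_prog, best_raw, stats = None, np.inf, []
    for gen in range(cfg.generations):
        pool = list({tuple(p): p for p in population}.values())
        raw = np.array([fitness(prog, grid, targets) for prog in pool])
        sizes = np.array([len(prog) for prog in pool], dtype=float)
        penalized = raw + parsimony * sizes

        gen_best = int(np.lexsort((sizes, raw))[0])
        if raw[gen_best] < best_raw or (raw[gen_best] == best_raw and
                                        best_prog is not None and
                                        sizes[gen_best] < len(best_prog)):
            best_raw = float(raw[gen_best])
            best_prog = list(pool[gen_best])
        stats.append({
            "generation": gen,
            "best_raw_mse": best_raw,
            "best_penalized": float(np.min(penalized)),
            "median_nodes": float(np.median(sizes)),
        })
        if best_raw < cfg.stopping_criteria or gen == cfg.generations - 1:
            break

        def tournament():
            idx = rng.integers(len(pool), size=min(cfg.tournament_size, len(pool)))
            return pool[idx[np.argmin(penalized[idx])]]

        def brood(maker):
            cands = [maker() for _ in range(cfg.brood_size)]
            f = [fitness(c, grid, targets) + parsimony * len(c) for c in cands]
            return cands[int(np.argmin(f))]

        nxt = [list(best_prog)]  # elite
        while len(nxt) < cfg.population_size:
            r = rng.random()
            parent = tournament()
            if r < p_cx:
                donor = tournament()
                nxt.append(brood(lambda: _crossover(rng, parent, donor)))
            elif r < p_sub:
                nxt.append(brood(lambda: _subtree_mutation(rng, parent, cfg)))
            elif r < p_hoist:
                nxt.append(brood(lambda: _hoist_mutation(rng, parent)))
            elif r < p_point:
                nxt.append(brood(lambda: _point_mutation(rng, parent, cfg)))
            else:
                nxt.append(list(parent))
        population = nxt

    return ExprTree(best_prog), stats


# ---------------------------------------------------------------------------
# the closed-form reference oviposition expression


def eval_reference(T, R):
    """The fixed reference oviposition expression (eggs/adult/day).

    ``16 * sigmoid(phi) + 4`` with
    ``phi = T - (16 - 1.3593*R*T*sigmoid(-0.3427*R)
                 + 16.0729*sigmoid(1.0742*T - 1.3593*R*T) + 7.9271)``,
    written with saturating logistic terms so extreme inputs cannot
    overflow. Output lies strictly inside (4, 20) for all finite (T, R).
    """
    T = np.asarray(T, dtype=float)
    R = np.asarray(R, dtype=float)
    interaction = 1.3593 * R * T
    phi = T - (16.0 - interaction * expit(-0.3427 * R)
               + 16.0729 * expit(1.0742 * T - interaction) + 7.9271)
    out = (REFERENCE_UPPER - REFERENCE_LOWER) * expit(phi) + REFERENCE_LOWER
    return float(out) if out.ndim == 0 else out


def reference_lower_asymptote() -> float:
    """Infimum of the reference expression: the logistic term's lower limit."""
    span = REFERENCE_UPPER - REFERENCE_LOWER
    return float(span * expit(-np.inf) + REFERENCE_LOWER)


def validate_against_network(tree, net) -> float:
    """MSE between a distilled tree and the network on the validation grid."""
    from .oviposition_net import forward

    grid = validation_grid()
    targets = forward(net, grid[:, 0], grid[:, 1])
    return fitness(tree, grid, targets)
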