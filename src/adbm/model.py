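"""The allometric diet breadth model (ADBM).

The ADBM predicts each consumer's prey set from body masses alone, using
optimal foraging theory (the contingency model). Four traits are built
allometrically from the body masses M (grams):

* prey energy content        ``E_i = e * M_i``
* prey density               ``N_i = n * M_i**ni``            (ni = -3/4)
* space clearance (attack)   ``A_ij = a * M_i**ai * M_j**aj``
* handling time              ``H_ij = h / (b - M_i/M_j)``  if ``M_i/M_j < b``,
  else infinite (the prey is too large relative to the consumer to handle).

With encounter rate ``lambda_ij = A_ij * N_i`` and profitability
``P_ij = E_i / H_ij``, consumer j's diet is built by the contingency rule:
rank feasible prey by decreasing profitability and add them while the next
item's profitability strictly exceeds the intake rate of the current diet D,

    R(D) = sum_{i in D} lambda_ij E_i / (1 + sum_{i in D} lambda_ij H_ij).

The first excluded item terminates the diet (the classical zero-one rule:
this prefix maximizes R over all prey subsets). The model is fully
deterministic: a community and a parameter point map to exactly one web.

Only ``a``, ``ai``, ``aj`` and ``b`` are free; ``e``, ``n`` and ``h`` are
fixed at 1 because predicted structure depends on the product n*a*h and is
unaffected by e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import TraitRangeError
from .webio import Community, PredationMatrix

__all__ = ["ADBMParams", "TraitTables", "build_traits", "optimal_diet", "predict_web"]

#: largest base-10 exponent representable in float64 with headroom
_LOG10_MAX = 300.0


@dataclass(frozen=True)
class ADBMParams:
    """One point in ADBM parameter space.

    ``a`` (space-clearance constant) and ``b`` (prey/consumer mass-ratio
    threshold for finite handling) must be positive; ``ai`` and ``aj`` are
    the prey- and consumer-mass exponents of the attack rate. The remaining
    constants are fixed by convention (see module docstring).
    """

    a: float
    ai: float
    aj: float
    b: float
    e: float = 1.0
    n: float = 1.0
    ni: float = -0.75
    h: float = 1.0

    def __post_init__(self):
        for name in ("a", "b", "e", "n", "h"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name} must be positive and finite, got {v}")
        for name in ("ai", "aj", "ni"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")

    @property
    def log10_a(self) -> float:
        return float(np.log10(self.a))

    @property
    def log10_b(self) -> float:
        return float(np.log10(self.b))


@dataclass(frozen=True)
class TraitTables:
    """Allometric trait values for one (community, parameters) pair.

    ``E`` and ``N`` are length-S vectors over prey; ``A`` and ``H`` are S x S
    matrices indexed (prey i, consumer j). Infinite handling is encoded as
    ``+inf``, never a large sentinel.
    """

    E: np.ndarray
    N: np.ndarray
    A: np.ndarray
    H: np.ndarray


def build_traits(community: Community, params: ADBMParams) -> TraitTables:
    """Evaluate the four allometric trait relationships for a community.

    Powers are evaluated in log10 space so that communities spanning many
    orders of magnitude of body mass do not overflow; a genuinely
    unrepresentable magnitude raises :class:`TraitRangeError` naming the
    species and the exponent involved.
    """
    M = community.masses
    logM = np.log10(M)

    E = params.e * M

    logN = np.log10(params.n) + params.ni * logM
    if np.abs(logN).max() > _LOG10_MAX:
        k = int(np.argmax(np.abs(logN)))
        raise TraitRangeError(
            f"density N overflows for species {community.node_ids[k]!r} (exponent ni={params.ni})"
        )
    N = 10.0**logN

    logA = np.log10(params.a) + params.ai * logM[:, None] + params.aj * logM[None, :]
    if np.abs(logA).max() > _LOG10_MAX:
        i, j = np.unravel_index(int(np.argmax(np.abs(logA))), logA.shape)
        raise TraitRangeError(
            f"attack rate A overflows for prey {community.node_ids[i]!r} / "
            f"consumer {community.node_ids[j]!r} (exponents ai={params.ai}, aj={params.aj})"
        )
    A = 10.0**logA

    log_ratio = logM[:, None] - logM[None, :]
    with np.errstate(over="ignore"):
        ratio = 10.0**log_ratio
    feasible = ratio < params.b
    with np.errstate(divide="ignore", over="ignore"):
        H = np.where(feasible, params.h / (params.b - ratio), np.inf)
    return TraitTables(E=E, N=N, A=A, H=H)


def optimal_diet(consumer_index: int, traits: TraitTables) -> set[int]:
    """Prey set maximizing consumer ``consumer_index``'s rate of energy intake.

    Reference scalar implementation of the contingency rule; the vectorized
    :func:`predict_web` must agree with it column by column.
    """
    E, N, A, H = traits.E, traits.N, traits.A[:, consumer_index], traits.H[:, consumer_index]
    finite = np.isfinite(H)
    with np.errstate(invalid="ignore"):
        P = np.where(finite, E / H, 0.0)
    candidates = [i for i in np.argsort(-P, kind="stable") if finite[i] and P[i] > 0]
    diet: list[int] = []
    num = 0.0  # sum lambda * E over the diet
    den = 1.0  # 1 + sum lambda * H
    for k in candidates:
        rate = num / den
        if P[k] > rate:
            lam = A[k] * N[k]
            diet.append(int(k))
            num += lam * E[k]
            den += lam * H[k]
        else:
            break
    return set(diet)


def predict_web(community: Community, params: ADBMParams) -> PredationMatrix:
    """Predict the full predation matrix for a community under ``params``.

    Column j is the indicator vector of consumer j's optimal diet. All S
    diets are computed at once: prey are ranked per column by profitability
    (stable sort, so ties fall back to the canonical mass-then-label order),
    prefix intake rates are accumulated, and each diet is cut at the first
    prey whose profitability does not exceed the intake rate of the prefix
    before it.
    """
    traits = build_traits(community, params)
    S = community.size
    finite = np.isfinite(traits.H)
    with np.errstate(invalid="ignore"):
        P = np.where(finite, traits.E[:, None] / traits.H, 0.0)

    order = np.argsort(-P, axis=0, kind="stable")  # per-column profitability ranking
    cols = np.arange(S)[None, :]
    P_sorted = np.take_along_axis(P, order, axis=0)

    lam = traits.A * traits.N[:, None]
    contribE = np.where(finite, lam * traits.E[:, None], 0.0)
    contribH = np.where(finite, lam * traits.H, 0.0)
    cE = np.cumsum(np.take_along_axis(contribE, order, axis=0), axis=0)
    cH = np.cumsum(np.take_along_axis(contribH, order, axis=0), axis=0)

    # intake rate of the prefix *before* each ranked item
    rate_prev = np.vstack([np.zeros((1, S)), cE[:-1] / (1.0 + cH[:-1])])
    include = P_sorted > rate_prev
    # stop at the first exclusion: items after it never enter the diet
    keep = np.cumprod(include, axis=0).astype(bool)

    links = np.zeros((S, S), dtype=np.int8)
    links[order[keep], np.broadcast_to(cols, (S, S))[keep]] = 1
    return PredationMatrix(community, links)
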