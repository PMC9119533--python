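"""Synthetic tract data with a known grade-effect gradient.

Real redlining analyses start from two tables that are expensive to build:
a per-tract composition of land-area coverage by the four HOLC grades
(A "best" ... D "hazardous") plus unrated space (U), and a set of
present-day tract outcomes (life expectancy, health prevalences, mobility
metrics). This module emulates both so every downstream stage — scheme
assignment, cross-validation, meta-regression, collapse, validation — can
be exercised and tested without external census or health data.

The generator encodes the qualitative structure the historical maps
produce: most tracts intersect several differently graded areas, a
substantial share of each tract is unrated, and outcomes follow a monotone
grade gradient (A best, D worst) shared across mutually correlated
outcome variables, plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RATED_GRADES: tuple[str, ...] = ("A", "B", "C", "D")
ALL_GRADES: tuple[str, ...] = ("A", "B", "C", "D", "U")
COVERAGE_COLUMNS: tuple[str, ...] = (
    "tract_id", "pct_a", "pct_b", "pct_c", "pct_d", "pct_u",
)

#: default grade effects: monotone A > B > C > D; magnitudes arbitrary
DEFAULT_GRADE_WEIGHTS: Mapping[str, float] = {
    "A": 1.0, "B": 0.5, "C": 0.0, "D": -0.5,
}

# Marginal grade frequencies used when sampling which grades cover a
# random tract; skewed toward C and D like the historical maps, where C
# ("definitely declining") covered the largest area.
_GRADE_INCLUSION_P = np.array([0.12, 0.22, 0.36, 0.30])

# P(tract intersects exactly m differently graded areas); about 60% of
# tracts touch two or more grades.
_N_GRADES_P = np.array([0.40, 0.35, 0.18, 0.07])


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic tract universe.

    Parameters
    ----------
    n_tracts:
        Number of tracts to generate.
    grade_weights:
        Effect of full coverage by each rated grade on the latent
        neighborhood-quality score ``L``; the default is a monotone
        A > B > C > D gradient.
    rank_decay:
        Geometric decay of a grade's influence on ``L`` by coverage
        rank (see :func:`latent_quality`); lower values concentrate the
        gradient on the dominant grade.
    noise_sd:
        Total non-gradient standard deviation added to every outcome,
        split between a shared and an idiosyncratic component.
    n_outcomes:
        Number of outcome columns (``y1`` .. ``yK``).
    shared_signal_frac:
        Fraction of the noise *variance* that is shared across outcomes;
        drives the inter-outcome correlation (and hence Cronbach's alpha
        of the outcome battery).
    sign_flips:
        Outcome indices (0-based) whose sign is inverted, emulating
        "bad" outcomes such as disease prevalences where higher = worse.
    ensure_all_combinations:
        When true, the first tracts enumerate every ordered rank
        combination of 1-4 rated grades, each both with and without a
        nonzero unrated share, so that every feasible rank-ordered class
        occurs in the data.
    seed:
        Seed for all randomness in the generator.
    """

    n_tracts: int = 1500
    grade_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_WEIGHTS)
    )
    rank_decay: float = 0.4
    noise_sd: float = 0.35
    n_outcomes: int = 6
    shared_signal_frac: float = 0.55
    sign_flips: frozenset[int] = frozenset()
    ensure_all_combinations: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracts <= 0:
            raise ValueError("n_tracts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 < self.rank_decay <= 1.0:
            raise ValueError("rank_decay must be in (0, 1]")
        if self.n_outcomes <= 0:
            raise ValueError("n_outcomes must be positive")
        if not 0.0 <= self.shared_signal_frac <= 1.0:
            raise ValueError("shared_signal_frac must be in [0, 1]")
        missing = [g for g in RATED_GRADES if g not in self.grade_weights]
        if missing:
            raise ValueError(f"grade_weights missing grades: {missing}")
        object.__setattr__(self, "sign_flips", frozenset(self.sign_flips))
        bad = [j for j in self.sign_flips if not 0 <= j < self.n_outcomes]
        if bad:
            raise ValueError(f"sign_flips indices out of range: {bad}")


def rank_combinations(max_len: int = 4, grades: Sequence[str] = RATED_GRADES):
    """All ordered rank combinations of 1..max_len distinct grades.

    For the four rated grades this enumerates 4 singles, 12 pairs,
    24 triples and 24 quadruples = 64 combinations.
    """
    combos: list[tuple[str, ...]] = []
    for m in range(1, max_len + 1):
        combos.extend(permutations(grades, m))
    return combos


def _enforced_rows(rng: np.random.Generator) -> list[np.ndarray]:
    """Compositions covering every rank combination, with and without U.

    Rows are vectors over (A, B, C, D, U) summing to 100 with strictly
    decreasing coverages across the present rated grades.
    """
    rows = []
    for combo in rank_combinations():
        for with_u in (False, True):
            m = len(combo)
            shares = _strictly_decreasing_shares(rng, m)
            u = rng.uniform(5.0, 60.0) if with_u else 0.0
            vec = np.zeros(5)
            for g, s in zip(combo, shares * (100.0 - u)):
                vec[RATED_GRADES.index(g)] = s
            vec[4] = u
            rows.append(vec)
    return rows


def _strictly_decreasing_shares(rng: np.random.Generator, m: int) -> np.ndarray:
    """Dirichlet draw sorted descending; redraw on (measure-zero) ties."""
    while True:
        shares = np.sort(rng.dirichlet(np.full(m, 2.0)))[::-1]
        if m == 1 or np.all(np.diff(shares) < 0):
            return shares


def generate_coverages(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a tract coverage table.

    Returns a data frame with columns ``tract_id, pct_a, pct_b, pct_c,
    pct_d, pct_u``; each row is a composition over {A, B, C, D, U}
    summing to 100. Fully unrated tracts (100% U) are never emitted:
    the study universe is tracts with at least some rated coverage.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[np.ndarray] = []
    if config.ensure_all_combinations:
        rows = _enforced_rows(rng)
        if config.n_tracts < len(rows):
            raise ValueError(
                f"n_tracts={config.n_tracts} cannot host all "
                f"{len(rows)} enforced rank-order combinations; "
                f"need at least {len(rows)} "
                f"({len(rows) - config.n_tracts} more)"
            )
    n_random = config.n_tracts - len(rows)
    for _ in range(n_random):
        m = 1 + rng.choice(4, p=_N_GRADES_P)
        grades = rng.choice(
            4, size=m, replace=False,
            p=_GRADE_INCLUSION_P / _GRADE_INCLUSION_P.sum(),
        )
        shares = _strictly_decreasing_shares(rng, m)
        # unrated share drawn independently, then the rated part is
        # rescaled so the composition sums to 100; ~15% of tracts are
        # fully rated, the rest average roughly a third unrated
        u = 0.0 if rng.random() < 0.15 else min(100.0 * rng.beta(0.9, 1.9), 99.5)
        vec = np.zeros(5)
        vec[grades] = shares * (100.0 - u)
        vec[4] = u
        rows.append(vec)
    mat = np.asarray(rows)
    mat *= 100.0 / mat.sum(axis=1, keepdims=True)
    width = max(6, len(str(config.n_tracts)))
    ids = [f"S{i:0{width}d}" for i in range(1, config.n_tracts + 1)]
    out = pd.DataFrame(mat, columns=["pct_a", "pct_b", "pct_c", "pct_d", "pct_u"])
    out.insert(0, "tract_id", ids)
    return out


#: geometric decay of grade influence by coverage rank
DEFAULT_RANK_DECAY = 0.4


def latent_quality(coverages: pd.DataFrame,
                   grade_weights: Mapping[str, float] | None = None,
                   rank_decay: float = DEFAULT_RANK_DECAY) -> pd.Series:
    """Rank-weighted latent neighborhood quality.

    The rated grades present in a tract are ordered by covered area; the
    latent score is the weight of the dominant grade blended with the
    lower-ranked grades' weights at geometrically declining influence:

        L = sum_r kappa_r * w_{g_(r)},   kappa_r ∝ rank_decay**(r-1),

    normalized so the kappas sum to 1 over the grades present. Two
    structural features of the historical data are built in: the unrated
    share carries no signal (unrated land was simply not developed at
    rating time — missing at random), and the outcome landscape depends
    on *which* grades cover a tract and their rank order, far more than
    on the exact percentages. A tract fully covered by one grade scores
    exactly that grade's weight.
    """
    w = dict(DEFAULT_GRADE_WEIGHTS if grade_weights is None else grade_weights)
    P = coverages[[f"pct_{g.lower()}" for g in RATED_GRADES]].to_numpy()
    if np.any(P.sum(axis=1) <= 0.0):
        raise ValueError("fully unrated tract has no defined latent quality")
    wvec = np.array([w[g] for g in RATED_GRADES])
    order = np.argsort(-P, axis=1, kind="stable")
    ranked_w = np.take_along_axis(np.broadcast_to(wvec, P.shape), order, axis=1)
    present = np.take_along_axis(P, order, axis=1) > 0.0
    kappa = np.where(present, rank_decay ** np.arange(4), 0.0)
    kappa /= kappa.sum(axis=1, keepdims=True)
    L = (kappa * ranked_w).sum(axis=1)
    return pd.Series(L, index=coverages.index, name="latent_quality")


def generate_outcomes(coverages: pd.DataFrame,
                      config: SyntheticConfig) -> pd.DataFrame:
    """Generate correlated tract outcomes driven by the grade gradient.

    Each outcome is ``y_j = intercept_j + slope_j * L + shared + noise``
    where ``L`` is the latent quality score implied by the coverage
    composition, ``shared`` is a tract-level noise component common to
    all outcomes and ``noise`` is idiosyncratic. Outcomes listed in
    ``config.sign_flips`` are negated, emulating outcomes where higher
    values are worse. Slopes default to 1 for every outcome and are
    recorded in ``DataFrame.attrs['slopes']`` for parameter-recovery
    checks.
    """
    if len(coverages) == 0:
        raise ValueError("coverages is empty; cannot generate outcomes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(coverages)
    K = config.n_outcomes
    L = latent_quality(coverages, config.grade_weights,
                       config.rank_decay).to_numpy()
    shared_sd = config.noise_sd * np.sqrt(config.shared_signal_frac)
    idio_sd = config.noise_sd * np.sqrt(1.0 - config.shared_signal_frac)
    shared = shared_sd * rng.standard_normal(n)
    slopes = np.ones(K)
    intercepts = np.zeros(K)
    ys = np.empty((n, K))
    for j in range(K):
        y = intercepts[j] + slopes[j] * L + shared + idio_sd * rng.standard_normal(n)
        if j in config.sign_flips:
            y = -y
        ys[:, j] = y
    out = pd.DataFrame(ys, columns=[f"y{j + 1}" for j in range(K)],
                       index=coverages.index)
    out.insert(0, "tract_id", coverages["tract_id"].to_numpy())
    out.attrs["slopes"] = slopes.tolist()
    out.attrs["intercepts"] = intercepts.tolist()
    out.attrs["sign_flips"] = sorted(config.sign_flips)
    return out


# ---------------------------------------------------------------------------
# polygon fixtures


def _box(minx: float, miny: float, maxx: float, maxy: float):
    from shapely.geometry import box

    if maxx <= minx or maxy <= miny:
        raise ValueError(
            f"degenerate rectangle ({minx}, {miny}, {maxx}, {maxy}): "
            "zero or negative area"
        )
    return box(minx, miny, maxx, maxy)


#: default planar test bed: a tract fully inside one grade, one split
#: 50/50 rated/unrated, one covered 40% D + 25% B, one untouched, and one
#: split across two grades. All overlap areas are analytically known.
DEFAULT_GRID_SPEC: dict = {
    "tracts": [
        ("T1", (0.0, 0.0, 1.0, 1.0)),    # fully inside A
        ("T2", (2.0, 0.0, 3.0, 1.0)),    # left half B, right half unrated
        ("T3", (4.0, 0.0, 5.0, 1.0)),    # 40% D, 25% B, 35% unrated
        ("T4", (6.0, 0.0, 7.0, 1.0)),    # untouched
        ("T5", (8.0, 0.0, 9.0, 1.0)),    # 60% C / 40% D, fully rated
    ],
    "holc": [
        ("A", (-0.2, -0.2, 1.2, 1.2)),
        ("B", (2.0, 0.0, 2.5, 1.0)),
        ("D", (4.0, 0.0, 4.4, 1.0)),
        ("B", (4.75, 0.0, 5.0, 1.0)),
        ("C", (8.0, 0.0, 8.6, 1.0)),
        ("D", (8.6, 0.0, 9.0, 1.0)),
    ],
}


def generate_polygon_fixture(grid_spec: dict | None = None):
    """Build rectangular tract and graded-area polygon layers.

    ``grid_spec`` maps ``"tracts"`` to ``(tract_id, (minx, miny, maxx,
    maxy))`` pairs and ``"holc"`` to ``(grade, bbox)`` pairs in planar
    coordinates. Returns ``(tracts, holc)`` as lists of ``(tract_id,
    Polygon)`` and ``(grade, Polygon)``. The default spec has analytically
    known overlap areas and exercises full coverage, grade splits,
    partial un-ratedness and an untouched tract.
    """
    spec = DEFAULT_GRID_SPEC if grid_spec is None else grid_spec
    tracts = [(tid, _box(*bbox)) for tid, bbox in spec["tracts"]]
    holc = [(grade, _box(*bbox)) for grade, bbox in spec["holc"]]
    return tracts, holc
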