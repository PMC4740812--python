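"""Discrete-time Markov-chain model of TBP promoter microstates.

A single promoter is modelled as a five-state Markov chain over the
microstates

* ``f`` — free promoter (no TBP bound),
* ``T`` — monomeric TBP bound at the TBS,
* ``M`` — TBS:TBP:Mot1p (Mot1p engaged the DNA-bound TBP monomer),
* ``S`` — TBS:TBP:SAGA (SAGA engaged the monomer; transcribing),
* ``D`` — TBS:TBP:TFIID (TFIID assembled as a holo-complex; transcribing).

``S`` and ``D`` form the transcriptional "On" macrostate, ``f``/``T``/``M``
the "Off" macrostate.  The transition graph encodes the promoter decision
tree: a free promoter either binds monomeric TBP (``f -> T``) or recruits
the TFIID holo-complex directly (``f -> D``); DNA-bound monomeric TBP is
either spontaneously lost (``T -> f``) or engaged by a partner, with the
competition parameter deciding whether that partner is Mot1p (``T -> M``)
or SAGA (``T -> S``); every engaged complex eventually dissociates back to
the free promoter.  All other transitions are zero — in particular TFIID
never completes around pre-bound monomeric TBP (``T -> D`` is 0).

Mean residence times map to geometric exit probabilities (mean ``r`` steps
in a state corresponds to a per-step exit probability ``1/r``), the
memoryless discrete-time analogue of a residence time.

A population of cells is simulated as independent chains; expression
accrues per time step spent in an On state (no degradation is modelled)
and population noise is the coefficient of variation of the per-cell
totals.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MICROSTATES",
    "ON_STATES",
    "OFF_STATES",
    "PromoterParams",
    "SimulationResult",
    "PhaseDiagram",
    "TATA_BOX_PARAMS",
    "TATA_LIKE_PARAMS",
    "build_transition_matrix",
    "simulate_population",
    "population_noise",
    "stationary_distribution",
    "waiting_time_stats",
    "turnover_rate",
    "affinity_sweep",
    "sweep_phase_diagram",
]

#: Microstate labels in canonical matrix order.
MICROSTATES: tuple[str, ...] = ("f", "T", "M", "S", "D")
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(MICROSTATES)}

#: Transcribing (On) and silent (Off) macrostate members.
ON_STATES: frozenset[str] = frozenset({"S", "D"})
OFF_STATES: frozenset[str] = frozenset({"f", "T", "M"})

_ON_IDX = np.array([STATE_INDEX[s] for s in sorted(ON_STATES)])
_S_IDX = STATE_INDEX["S"]
_D_IDX = STATE_INDEX["D"]
_T_IDX = STATE_INDEX["T"]
_F_IDX = STATE_INDEX["f"]


class ParameterError(ValueError):
    """A promoter parameter violates its admissible range."""


@dataclass(frozen=True)
class PromoterParams:
    """Kinetic parameters of one promoter archetype.

    Parameters
    ----------
    affinity
        Per-step probability that the free promoter binds monomeric TBP
        (``f -> T``).  High for TATA-box sites, near zero for TATA-like.
    tfiid_recruit
        Per-step probability of direct TFIID holo-complex assembly on the
        free promoter (``f -> D``).
    engage
        Per-step probability that DNA-bound monomeric TBP is engaged by a
        partner complex (Mot1p or SAGA).
    competition
        Probability that the engaging partner is Mot1p rather than SAGA.
        Mot1p evicts TBP without transcription; SAGA initiates it.
    t_off
        Per-step spontaneous dissociation probability of the TBP:TBS
        complex (``T -> f``).
    residence_m, residence_s, residence_d
        Mean residence times (in steps, >= 1) of the Mot1p, SAGA and
        TFIID complexes.  Mot1p turns over fast, TFIID is stable, SAGA
        is intermediate.
    burst_s, burst_d
        Expression units accrued per step spent in the S and D states.
        SAGA-driven initiation produces the larger burst.
    """

    affinity: float = 0.5
    tfiid_recruit: float = 0.1
    engage: float = 0.8
    competition: float = 0.9
    t_off: float = 0.05
    residence_m: float = 2.0
    residence_s: float = 10.0
    residence_d: float = 50.0
    burst_s: float = 5.0
    burst_d: float = 1.0

    def __post_init__(self) -> None:
        probs = {
            "affinity": self.affinity,
            "tfiid_recruit": self.tfiid_recruit,
            "engage": self.engage,
            "competition": self.competition,
            "t_off": self.t_off,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name}={value!r} must lie in [0, 1]")
        if self.affinity + self.tfiid_recruit > 1.0 + 1e-12:
            raise ParameterError(
                "affinity + tfiid_recruit must not exceed 1 "
                f"(got {self.affinity} + {self.tfiid_recruit})"
            )
        if self.engage + self.t_off > 1.0 + 1e-12:
            raise ParameterError(
                "engage + t_off must not exceed 1 "
                f"(got {self.engage} + {self.t_off})"
            )
        for name in ("residence_m", "residence_s", "residence_d"):
            if getattr(self, name) < 1.0:
                raise ParameterError(f"{name} must be >= 1 step")
        for name in ("burst_s", "burst_d"):
            if getattr(self, name) < 0.0:
                raise ParameterError(f"{name} must be >= 0")

    def replace(self, **overrides: float) -> "PromoterParams":
        """Return a copy with the given fields overridden (re-validated)."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: TATA-box archetype: strong monomeric TBP binding, weak direct TFIID
#: recruitment, Mot1p-dominant competition.
TATA_BOX_PARAMS = PromoterParams(affinity=0.5, tfiid_recruit=0.1)

#: TATA-like archetype: TBP arrives almost exclusively within the TFIID
#: holo-complex.  The total per-step binding propensity (affinity +
#: tfiid_recruit = 0.6) matches the TATA-box archetype so the two differ
#: only in how TBP is delivered, not in how often.
TATA_LIKE_PARAMS = PromoterParams(affinity=0.05, tfiid_recruit=0.55)


def build_transition_matrix(params: PromoterParams) -> np.ndarray:
    """Build the 5x5 row-stochastic transition matrix for one promoter.

    Rows/columns follow :data:`MICROSTATES` order ``(f, T, M, S, D)``.
    Residual probability mass in each row is the self-transition.
    """
    if not isinstance(params, PromoterParams):
        params = PromoterParams(**params)  # re-validate plain dicts
    a, p_d = params.affinity, params.tfiid_recruit
    p_e, c, t_off = params.engage, params.competition, params.t_off
    m = np.zeros((5, 5))
    m[_F_IDX] = [1.0 - a - p_d, a, 0.0, 0.0, p_d]
    m[_T_IDX] = [t_off, 1.0 - t_off - p_e, p_e * c, p_e * (1.0 - c), 0.0]
    for idx, r in (
        (STATE_INDEX["M"], params.residence_m),
        (STATE_INDEX["S"], params.residence_s),
        (STATE_INDEX["D"], params.residence_d),
    ):
        m[idx, _F_IDX] = 1.0 / r
        m[idx, idx] = 1.0 - 1.0 / r
    # guard against accumulated floating error: rows must sum to one
    np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
    return m


def _check_stochastic(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (5, 5):
        raise ValueError(f"transition matrix must be 5x5, got {matrix.shape}")
    if (matrix < -1e-12).any() or (matrix > 1 + 1e-12).any():
        raise ValueError("transition probabilities must lie in [0, 1]")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    return matrix


@dataclass
class SimulationResult:
    """Outcome of simulating a cell population at one promoter.

    Attributes
    ----------
    histories
        ``(n_cells, n_steps)`` integer array of microstate indices into
        :data:`MICROSTATES`; entry ``[i, t]`` is cell *i*'s state after
        transition step ``t + 1`` (all cells start in ``f`` at step 0,
        which is not recorded).
    expression
        Per-cell cumulative expression totals.
    """

    histories: np.ndarray
    expression: np.ndarray
    params: PromoterParams
    seed: int

    @property
    def n_cells(self) -> int:
        return self.histories.shape[0]

    @property
    def n_steps(self) -> int:
        return self.histories.shape[1]

    def history_labels(self, cell: int) -> list[str]:
        """Microstate labels of one cell's trajectory."""
        return [MICROSTATES[i] for i in self.histories[cell]]

    def expression_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell": np.arange(self.n_cells), "expression": self.expression}
        )


def _cell_uniforms(seed: int, n_cells: int, n_steps: int) -> np.ndarray:
    """Per-cell uniform variates from independent deterministic streams.

    Cell *i*'s stream depends only on ``(seed, i)``, so enlarging the
    population extends, rather than reshuffles, an earlier run.
    """
    u = np.empty((n_cells, n_steps))
    for i in range(n_cells):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        )
        u[i] = rng.random(n_steps)
    return u


def simulate_population(
    matrix: np.ndarray,
    params: PromoterParams,
    n_cells: int = 500,
    n_steps: int = 150,
    seed: int = 0,
    burn_in: int = 0,
    burst_per_entry: bool = False,
) -> SimulationResult:
    """Simulate ``n_cells`` independent promoter chains for ``n_steps``.

    Every cell starts in the free state.  Expression accrues
    ``burst_s`` per step in S and ``burst_d`` per step in D (with
    ``burst_per_entry=True``, per *entry* into the state instead).  No
    degradation term is applied.  With ``burn_in > 0`` the first
    ``burn_in`` recorded steps are discarded from both histories and
    expression.
    """
    matrix = _check_stochastic(matrix)
    if n_cells < 1 or n_steps < 1:
        raise ValueError("n_cells and n_steps must be >= 1")
    total_steps = n_steps + burn_in
    cum = np.cumsum(matrix, axis=1)
    cum[:, -1] = 1.0  # close the last bin against rounding
    u = _cell_uniforms(seed, n_cells, total_steps)
    states = np.full(n_cells, _F_IDX, dtype=np.int64)
    histories = np.empty((n_cells, total_steps), dtype=np.int8)
    for t in range(total_steps):
        rows = cum[states]  # (n_cells, 5)
        states = (u[:, t, None] < rows).argmax(axis=1)
        histories[:, t] = states
    histories = histories[:, burn_in:]
    if burst_per_entry:
        prev = np.concatenate(
            [np.full((n_cells, 1), _F_IDX, dtype=np.int8), histories[:, :-1]],
            axis=1,
        )
        s_events = ((histories == _S_IDX) & (prev != _S_IDX)).sum(axis=1)
        d_events = ((histories == _D_IDX) & (prev != _D_IDX)).sum(axis=1)
    else:
        s_events = (histories == _S_IDX).sum(axis=1)
        d_events = (histories == _D_IDX).sum(axis=1)
    expression = params.burst_s * s_events + params.burst_d * d_events
    return SimulationResult(
        histories=histories,
        expression=expression.astype(float),
        params=params,
        seed=seed,
    )


def population_noise(result: SimulationResult | np.ndarray) -> float:
    """Coefficient of variation (sample s.d. / mean) of per-cell expression.

    Returns NaN (with a warning) when the population mean is zero; the
    CV is undefined there rather than infinite.
    """
    expr = (
        result.expression
        if isinstance(result, SimulationResult)
        else np.asarray(result, dtype=float)
    )
    if expr.size < 2:
        raise ValueError("population noise needs at least 2 cells")
    mean = expr.mean()
    if mean == 0.0:
        warnings.warn("zero mean expression: CV undefined", stacklevel=2)
        return float("nan")
    return float(expr.std(ddof=1) / mean)


def stationary_distribution(
    matrix: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix by power iteration.

    Starts from the uniform distribution and multiplies by the matrix
    until the L1 change drops below ``tol``.  Reducible chains converge
    to a component-dependent fixed point; a warning is emitted when the
    chain is visibly reducible (some state unreachable from ``f``).
    """
    matrix = _check_stochastic(matrix)
    reach = _reachable_from(matrix, _F_IDX)
    if len(reach) < 5:
        warnings.warn(
            "chain is reducible: states "
            f"{[MICROSTATES[i] for i in range(5) if i not in reach]} "
            "unreachable from f; result restricted to the reachable set",
            stacklevel=2,
        )
    pi = np.full(5, 0.2)
    for _ in range(max_iter):
        nxt = pi @ matrix
        if np.abs(nxt - pi).sum() < tol:
            return nxt / nxt.sum()
        pi = nxt
    raise RuntimeError(
        f"power iteration did not converge within {max_iter} iterations"
    )


def _reachable_from(matrix: np.ndarray, start: int) -> set[int]:
    seen = {start}
    frontier = [start]
    while frontier:
        i = frontier.pop()
        for j in np.nonzero(matrix[i] > 0)[0]:
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    return seen


@dataclass
class WaitingTimeStats:
    """Summary of Off-run lengths separating transcriptional On visits."""

    per_cell: list[np.ndarray]
    pooled: np.ndarray
    mean: float
    median: float
    no_on_state: bool = False


def waiting_time_stats(
    result: SimulationResult, include_censored: bool = False
) -> WaitingTimeStats:
    """Lengths of maximal Off-state runs between visits to On states.

    For each cell, a waiting time is the length of a maximal run of
    ``{f, T, M}`` flanked on both sides by an On state (``S`` or ``D``).
    Leading and trailing runs are censored (the On boundary was never
    observed) and excluded unless ``include_censored`` is set.  When no
    cell ever reaches an On state the summary is empty and flagged.
    """
    on = np.isin(result.histories, _ON_IDX)
    per_cell: list[np.ndarray] = []
    for row in on:
        runs: list[int] = []
        on_positions = np.nonzero(row)[0]
        if on_positions.size == 0:
            if include_censored:
                runs.append(row.size)
            per_cell.append(np.array(runs, dtype=int))
            continue
        # interior gaps between consecutive On steps
        gaps = np.diff(on_positions) - 1
        runs.extend(int(g) for g in gaps if g > 0)
        if include_censored:
            lead = int(on_positions[0])
            trail = int(row.size - 1 - on_positions[-1])
            if lead > 0:
                runs.append(lead)
            if trail > 0:
                runs.append(trail)
        per_cell.append(np.array(runs, dtype=int))
    pooled = (
        np.concatenate(per_cell) if per_cell else np.array([], dtype=int)
    )
    if pooled.size == 0:
        warnings.warn(
            "no complete Off-runs observed (no On state reached?)",
            stacklevel=2,
        )
        return WaitingTimeStats(
            per_cell=per_cell,
            pooled=pooled,
            mean=float("nan"),
            median=float("nan"),
            no_on_state=not on.any(),
        )
    return WaitingTimeStats(
        per_cell=per_cell,
        pooled=pooled,
        mean=float(pooled.mean()),
        median=float(np.median(pooled)),
    )


def turnover_rate(result: SimulationResult) -> float:
    """TBP turnover: new TBP bindings per simulated time step.

    Counts transitions from the free promoter into a TBP-acquiring state
    (``f -> T`` or ``f -> D``; the initial cold start in ``f`` counts as
    a preceding free step), divides by the number of simulated steps,
    and averages over cells.
    """
    prev = np.concatenate(
        [
            np.full((result.n_cells, 1), _F_IDX, dtype=result.histories.dtype),
            result.histories[:, :-1],
        ],
        axis=1,
    )
    bindings = (
        (prev == _F_IDX)
        & ((result.histories == _T_IDX) | (result.histories == _D_IDX))
    ).sum(axis=1)
    return float((bindings / result.n_steps).mean())


def affinity_sweep(
    base: PromoterParams,
    affinities: np.ndarray,
    n_replicates: int = 3,
    n_cells: int = 500,
    n_steps: int = 150,
    seed: int = 0,
    couple_tfiid: bool = True,
) -> pd.DataFrame:
    """Replicate-averaged CV as a function of TBP binding affinity.

    With ``couple_tfiid`` (default) the total per-step TBP delivery
    propensity ``affinity + tfiid_recruit`` is held at the base value, so
    increasing the affinity shifts delivery from the TFIID holo-complex
    to monomeric TBP — the mechanism by which a better TBS makes the
    promoter burstier under Mot1p-dominant competition.
    """
    total = base.affinity + base.tfiid_recruit
    rows = []
    for k, a in enumerate(np.asarray(affinities, dtype=float)):
        if couple_tfiid:
            params = base.replace(affinity=a, tfiid_recruit=total - a)
        else:
            params = base.replace(affinity=a)
        matrix = build_transition_matrix(params)
        for rep in range(n_replicates):
            rep_seed = _derive_seed(seed, k, rep)
            res = simulate_population(
                matrix, params, n_cells=n_cells, n_steps=n_steps, seed=rep_seed
            )
            rows.append(
                {
                    "affinity": a,
                    "replicate": rep,
                    "seed": rep_seed,
                    "cv": population_noise(res),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PhaseDiagram:
    """CV landscape over (competition, SAGA residence) for two archetypes.

    ``table`` is long-format with one row per grid cell and replicate
    columns aggregated: competition, residence_s, cv_tata, cv_talike,
    cv_diff (= cv_tata - cv_talike), n_replicates, seeds used.
    """

    table: pd.DataFrame
    competition_grid: np.ndarray
    residence_grid: np.ndarray
    n_replicates: int
    seed: int


def _derive_seed(master: int, *indices: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and indices."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(indices))
    return int(ss.generate_state(1)[0] % (2**31))


def sweep_phase_diagram(
    base_tata: PromoterParams = TATA_BOX_PARAMS,
    base_talike: PromoterParams = TATA_LIKE_PARAMS,
    competition_grid: np.ndarray | None = None,
    residence_grid: np.ndarray | None = None,
    n_replicates: int = 3,
    n_cells: int = 500,
    n_steps: int = 150,
    seed: int = 0,
) -> PhaseDiagram:
    """Sweep competition and SAGA residence for both promoter archetypes.

    Every grid cell overrides ``competition`` and ``residence_s`` in both
    archetype parameter sets, simulates ``n_replicates`` populations per
    archetype and records replicate-averaged CVs and their difference.
    """
    if competition_grid is None:
        competition_grid = np.linspace(0.05, 0.95, 10)
    if residence_grid is None:
        residence_grid = np.unique(np.round(np.geomspace(2, 100, 10)))
    competition_grid = np.asarray(competition_grid, dtype=float)
    residence_grid = np.asarray(residence_grid, dtype=float)
    if competition_grid.size == 0 or residence_grid.size == 0:
        raise ValueError("phase-diagram grids must be non-empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for ci, c in enumerate(competition_grid):
        for ri, r_s in enumerate(residence_grid):
            try:
                p_tata = base_tata.replace(competition=c, residence_s=r_s)
                p_talike = base_talike.replace(competition=c, residence_s=r_s)
            except ParameterError as err:
                raise ParameterError(
                    f"grid cell (competition={c}, residence_s={r_s}): {err}"
                ) from err
            m_tata = build_transition_matrix(p_tata)
            m_talike = build_transition_matrix(p_talike)
            cvs_tata, cvs_talike, seeds = [], [], []
            for rep in range(n_replicates):
                rep_seed = _derive_seed(seed, ci, ri, rep)
                seeds.append(rep_seed)
                for m, p, acc in (
                    (m_tata, p_tata, cvs_tata),
                    (m_talike, p_talike, cvs_talike),
                ):
                    res = simulate_population(
                        m, p, n_cells=n_cells, n_steps=n_steps, seed=rep_seed
                    )
                    acc.append(population_noise(res))
            cv_tata = float(np.mean(cvs_tata))
            cv_talike = float(np.mean(cvs_talike))
            rows.append(
                {
                    "competition": float(c),
                    "residence_s": float(r_s),
                    "cv_tata": cv_tata,
                    "cv_talike": cv_talike,
                    "cv_diff": cv_tata - cv_talike,
                    "n_replicates": n_replicates,
                    "seeds": ",".join(map(str, seeds)),
                }
            )
    return PhaseDiagram(
        table=pd.DataFrame(rows),
        competition_grid=competition_grid,
        residence_grid=residence_grid,
        n_replicates=n_replicates,
        seed=seed,
    )
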