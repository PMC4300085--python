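"""Stochastic gating of IP3 receptor subunits, tetrameric channels and clusters.

The receptor subunit follows a sequential-binding scheme with three
regulatory sites: one for IP3, one activating Ca2+ site and one inhibitory
Ca2+ site.  Calcium can bind the activating site only after IP3 is bound,
and the inhibitory site only after the activating site is occupied.  This
yields a linear four-state chain

    X000  <->  X100  <->  X110  <->  X111

where the indices denote occupancy of the (IP3, activating Ca, inhibitory
Ca) sites.  A subunit is *active* only in ``X110``.  A channel is a tetramer
of four identical, independent subunits and conducts when at least three
subunits are active.  Channels are grouped into clusters of ``N`` channels
that share the local calcium concentration of one grid cell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import IntEnum
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "KineticParams",
    "SubunitState",
    "ChannelState",
    "ClusterState",
    "transition_rates",
    "step_subunit",
    "channel_is_open",
    "count_open",
    "stationary_distribution",
    "open_probability",
    "ignition_point",
    "enumerate_channel_configurations",
    "n_channel_configurations",
    "TimeStepError",
]

#: number of channels per cluster
DEFAULT_CLUSTER_SIZE = 64

#: subunits per tetrameric channel
SUBUNITS_PER_CHANNEL = 4

#: minimum number of active subunits for the channel to conduct
OPEN_THRESHOLD = 3


class SubunitState(IntEnum):
    """One of the four reachable occupancy patterns of a receptor subunit.

    Only sequential occupancies exist: IP3 first, then activating Ca2+,
    then inhibitory Ca2+.  Patterns such as ``X010`` or ``X101`` are
    unreachable and deliberately unrepresentable.
    """

    X000 = 0  # empty
    X100 = 1  # IP3 bound
    X110 = 2  # IP3 + activating Ca bound -- the active (conducting) state
    X111 = 3  # fully occupied, Ca-inhibited


#: the single active subunit state
ACTIVE_STATE = SubunitState.X110


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the sequential-binding subunit model.

    Defaults are the study's standard kinetic parameter set.

    Attributes
    ----------
    k1, k_1:
        IP3 on-rate ((uM s)^-1) and off-rate (s^-1).
    k2, k_2:
        Activating-Ca2+ on-rate ((uM s)^-1) and off-rate (s^-1).
    k3, k_3:
        Inhibitory-Ca2+ on-rate ((uM s)^-1) and off-rate (s^-1).
    ip3:
        Cytosolic IP3 concentration (uM), treated as constant.
    """

    k1: float = 24.0
    k_1: float = 32.0
    k2: float = 30.0
    k_2: float = 0.82
    k3: float = 3.6
    k_3: float = 0.064
    ip3: float = 0.5

    def __post_init__(self) -> None:
        for name in ("k1", "k_1", "k2", "k_2", "k3", "k_3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate constant {name} must be positive")
        if self.ip3 < 0:
            raise ValueError("ip3 concentration must be non-negative")


@dataclass
class ChannelState:
    """A tetrameric channel: exactly four subunits."""

    subunits: Tuple[SubunitState, SubunitState, SubunitState, SubunitState]

    def __post_init__(self) -> None:
        self.subunits = tuple(SubunitState(s) for s in self.subunits)
        if len(self.subunits) != SUBUNITS_PER_CHANNEL:
            raise ValueError("a channel has exactly 4 subunits")


@dataclass
class ClusterState:
    """A cluster of channels housed in a single grid cell."""

    channels: List[ChannelState]
    grid_index: int = 0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("cluster must contain at least one channel")

    @classmethod
    def all_closed(cls, n_channels: int = DEFAULT_CLUSTER_SIZE,
                   grid_index: int = 0) -> "ClusterState":
        ch = [ChannelState((SubunitState.X000,) * 4) for _ in range(n_channels)]
        return cls(channels=ch, grid_index=grid_index)


def transition_rates(state: SubunitState, ca: float,
                     params: KineticParams) -> Dict[SubunitState, float]:
    """Outgoing transition rates (s^-1) from ``state`` at local ``ca`` (uM).

    The chain is strictly sequential, so each state has at most two exits:

    * ``X000 -> X100`` at ``k1 * [IP3]``
    * ``X100 -> X000`` at ``k_1``;  ``X100 -> X110`` at ``k2 * ca``
    * ``X110 -> X100`` at ``k_2``;  ``X110 -> X111`` at ``k3 * ca``
    * ``X111 -> X110`` at ``k_3``
    """
    if ca < 0:
        raise ValueError(f"calcium concentration must be non-negative, got {ca}")
    state = SubunitState(state)
    if state == SubunitState.X000:
        return {SubunitState.X100: params.k1 * params.ip3}
    if state == SubunitState.X100:
        return {SubunitState.X000: params.k_1,
                SubunitState.X110: params.k2 * ca}
    if state == SubunitState.X110:
        return {SubunitState.X100: params.k_2,
                SubunitState.X111: params.k3 * ca}
    return {SubunitState.X110: params.k_3}


class TimeStepError(ValueError):
    """Raised when rate * dt is too large for the linearized update."""


def step_subunit(state: SubunitState, ca: float, dt: float,
                 rng: np.random.Generator,
                 params: KineticParams | None = None) -> SubunitState:
    """Advance a single subunit by one linearized Markov step.

    Transition probabilities are linearized as ``rate * dt`` and competing
    exits are resolved by a single categorical draw (stay probability is
    ``1 - sum(rate * dt)``), which avoids any ordering bias between the two
    exits of ``X100`` and ``X110``.

    Parameters
    ----------
    state:
        Current subunit state.
    ca:
        Local calcium concentration (uM).
    dt:
        Time step (s); ``total_rate * dt`` must stay below 1.
    rng:
        Seeded :class:`numpy.random.Generator`; exactly one uniform draw is
        consumed per call.
    params:
        Kinetic rate constants (defaults to the standard set).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params is None:
        params = KineticParams()
    rates = transition_rates(state, ca, params)
    total = sum(rates.values())
    if total * dt >= 1.0:
        raise TimeStepError(
            f"total exit probability {total * dt:.3f} >= 1; reduce dt "
            f"(currently {dt} s) for the linearized update to be valid")
    u = rng.random()
    acc = 0.0
    for succ, rate in rates.items():
        acc += rate * dt
        if u < acc:
            return succ
    return SubunitState(state)


def channel_is_open(channel: ChannelState) -> bool:
    """True iff at least three of the four subunits are active (``X110``)."""
    n_active = sum(1 for s in channel.subunits if s == ACTIVE_STATE)
    return n_active >= OPEN_THRESHOLD


def count_open(cluster: ClusterState) -> int:
    """Number of conducting channels in the cluster."""
    return sum(1 for ch in cluster.channels if channel_is_open(ch))


def stationary_distribution(ca: float,
                            params: KineticParams | None = None) -> np.ndarray:
    """Stationary occupancy probabilities of the four subunit states.

    The chain is a birth-death (linear) chain, so the stationary law
    satisfies detailed balance::

        pi(X100)/pi(X000) = k1*[IP3]/k_1
        pi(X110)/pi(X100) = k2*ca/k_2
        pi(X111)/pi(X110) = k3*ca/k_3

    Returns an array indexed by :class:`SubunitState` that sums to 1.
    """
    if ca < 0:
        raise ValueError("calcium concentration must be non-negative")
    if params is None:
        params = KineticParams()
    w = np.empty(4)
    w[SubunitState.X000] = 1.0
    w[SubunitState.X100] = w[SubunitState.X000] * params.k1 * params.ip3 / params.k_1
    w[SubunitState.X110] = w[SubunitState.X100] * params.k2 * ca / params.k_2
    w[SubunitState.X111] = w[SubunitState.X110] * params.k3 * ca / params.k_3
    return w / w.sum()


def open_probability(ca: float, params: KineticParams | None = None) -> float:
    """Stationary probability that a tetrameric channel conducts.

    With independent subunits and ``P_a = pi(X110)``, the 3-or-4-of-4 rule
    gives ``P_a**4 + 4 * P_a**3 * (1 - P_a)``.  As a function of calcium the
    curve is bell-shaped: it rises through activation at low ``ca`` and
    falls through inhibition at high ``ca``.
    """
    pa = float(stationary_distribution(ca, params)[ACTIVE_STATE])
    return pa ** 4 + 4.0 * pa ** 3 * (1.0 - pa)


def ignition_point(params: KineticParams | None = None) -> float:
    """Calcium concentration (uM) maximizing the stationary open probability.

    The open probability is bell-shaped in calcium (activation wins at low
    concentrations, inhibition at high ones); its interior maximum marks
    the most excitable operating point of the channel.  Located by scalar
    optimization on (0, 10) uM.
    """
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda ca: -open_probability(ca, params),
                          bounds=(1e-6, 10.0), method="bounded",
                          options={"xatol": 1e-9})
    return float(res.x)


def enumerate_channel_configurations() -> List[Tuple[SubunitState, ...]]:
    """All distinct ordered configurations of the four-subunit channel.

    Each subunit independently occupies one of four states, giving
    ``4**4 = 256`` configurations.
    """
    return list(itertools.product(list(SubunitState), repeat=SUBUNITS_PER_CHANNEL))


def n_channel_configurations() -> int:
    """Count of tetramer configurations (enumerated, not assumed)."""
    return len(enumerate_channel_configurations())
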