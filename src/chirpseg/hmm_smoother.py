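"""Post-hoc label smoothing with a configurable discrete-emission HMM.

The ensemble labels every frame independently, so a long run of one class is
occasionally punctuated by implausible single-frame interruptions.  Decoding
the per-frame labels through a hidden Markov model whose transition matrix
encodes the legal class adjacencies (for the beetle template: A and B chirps
can never be directly adjacent, so those transitions are structural zeros)
replaces the observed sequence with the most probable state path (Viterbi),
removing such interruptions.

Observations are the hard per-frame labels produced after IQR thresholding;
the observation alphabet equals the state set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InputError
from .ensemble import EnsembleOutput, apply_iqr_threshold

_RENORM_TOL = 1e-6


@dataclass
class HMMSpec:
    """State names plus initial / transition / emission probabilities.

    ``transition[i, j]`` is P(state j at t+1 | state i at t); ``emission[i, k]``
    is P(observed label k | state i), with observed labels indexed in the
    same order as ``states``.  Rows within ``1e-6`` of summing to one are
    renormalized silently; anything further off is a configuration error.
    """

    states: list
    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.states)
        if n < 1 or len(set(self.states)) != n:
            raise ConfigError("states must be non-empty and unique")
        self.initial = _validated_row(np.asarray(self.initial, dtype=np.float64), "initial", n)
        self.transition = np.vstack(
            [
                _validated_row(row, f"transition[{self.states[i]}]", n)
                for i, row in enumerate(np.asarray(self.transition, dtype=np.float64))
            ]
        )
        self.emission = np.vstack(
            [
                _validated_row(row, f"emission[{self.states[i]}]", None)
                for i, row in enumerate(np.asarray(self.emission, dtype=np.float64))
            ]
        )
        if self.transition.shape != (n, n):
            raise ConfigError("transition must be square (state x state)")
        if self.emission.shape[0] != n:
            raise ConfigError("emission needs one row per state")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name) -> int:
        try:
            return self.states.index(name)
        except ValueError:
            raise InputError(f"unknown state name: {name!r}") from None


def _validated_row(row: np.ndarray, name: str, n: int | None) -> np.ndarray:
    row = np.asarray(row, dtype=np.float64)
    if n is not None and row.shape != (n,):
        raise ConfigError(f"{name} must have length {n}")
    if np.any(row < 0):
        raise ConfigError(f"{name} contains negative probabilities")
    total = row.sum()
    if abs(total - 1.0) > _RENORM_TOL:
        raise ConfigError(f"{name} sums to {total:.6g}, expected 1")
    return row / total


def load_hmm_spec(config: dict) -> HMMSpec:
    """Build a validated :class:`HMMSpec` from a plain config mapping.

    Expected keys: ``states`` (list of names), ``initial`` (name -> prob or
    list), ``transition`` and ``emission`` (name -> row mapping or nested
    lists).
    """
    try:
        states = list(config["states"])
    except KeyError:
        raise ConfigError("HMM config must list 'states'") from None

    def _row_table(entry, what):
        if isinstance(entry, dict):
            rows = []
            for s in states:
                if s not in entry:
                    raise ConfigError(f"{what} is missing a row for state {s!r}")
                rows.append(_vector(entry[s], f"{what}[{s}]"))
            return np.vstack(rows)
        return np.asarray(entry, dtype=np.float64)

    def _vector(entry, what):
        if isinstance(entry, dict):
            unknown = set(entry) - set(states)
            if unknown:
                raise ConfigError(f"{what} names unknown states: {sorted(unknown)}")
            return np.array([float(entry.get(s, 0.0)) for s in states])
        return np.asarray(entry, dtype=np.float64)

    for key in ("initial", "transition", "emission"):
        if key not in config:
            raise ConfigError(f"HMM config must provide '{key}'")
    return HMMSpec(
        states=states,
        initial=_vector(config["initial"], "initial"),
        transition=_row_table(config["transition"], "transition"),
        emission=_row_table(config["emission"], "emission"),
    )


def beetle_template() -> HMMSpec:
    """Three-state chirp smoother: A, B and background X.

    Self-transitions are sticky (0.99) and the A<->B transitions are
    structural zeros because the two chirp types are never directly
    adjacent.  Each chirp state emits its own label with probability 0.9 and
    X otherwise; X emits X with probability 0.9 and splits the rest between
    the chirp labels.  All values are overridable through configuration.
    """
    return HMMSpec(
        states=["A", "B", "X"],
        initial=np.array([0.1, 0.1, 0.8]),
        transition=np.array(
            [
                [0.99, 0.0, 0.01],
                [0.0, 0.99, 0.01],
                [0.005, 0.005, 0.99],
            ]
        ),
        emission=np.array(
            [
                [0.9, 0.0, 0.1],
                [0.0, 0.9, 0.1],
                [0.05, 0.05, 0.9],
            ]
        ),
    )


def binary_template() -> HMMSpec:
    """Two-state smoother for binary (event vs background) labeling."""
    return HMMSpec(
        states=["Y", "X"],
        initial=np.array([0.2, 0.8]),
        transition=np.array([[0.99, 0.01], [0.01, 0.99]]),
        emission=np.array([[0.9, 0.1], [0.1, 0.9]]),
    )


def _observation_indices(observed_labels, spec: HMMSpec) -> np.ndarray:
    obs = []
    for lab in observed_labels:
        if isinstance(lab, (int, np.integer)):
            if not 0 <= int(lab) < spec.n_states:
                raise InputError(f"observation index {lab} out of range")
            obs.append(int(lab))
        else:
            obs.append(spec.state_index(lab))
    return np.asarray(obs, dtype=np.int64)


def viterbi_smooth(observed_labels, spec: HMMSpec):
    """Most probable state path given the observed per-frame labels.

    Runs in log space so structural zeros become ``-inf`` without
    underflow.  Ties are broken toward the lowest state index at every step
    (so among equally probable paths the one that is smallest when read from
    the last frame backwards is returned).  Output has the same length and
    label type (names in, names out; indices in, indices out).

    Raises
    ------
    InputError
        For an unknown label, or a zero-probability observation sequence
        (the message names the first impossible frame).
    """
    obs = _observation_indices(observed_labels, spec)
    t_len = len(obs)
    if t_len == 0:
        return type(observed_labels)() if isinstance(observed_labels, list) else np.array([], dtype=np.int64)
    with np.errstate(divide="ignore"):
        log_init = np.log(spec.initial)
        log_trans = np.log(spec.transition)
        log_emis = np.log(spec.emission)
    delta = log_init + log_emis[:, obs[0]]
    if np.all(np.isinf(delta)):
        raise InputError("observation sequence impossible at frame 0")
    back = np.zeros((t_len, spec.n_states), dtype=np.int64)
    for t in range(1, t_len):
        cand = delta[:, None] + log_trans  # (from, to)
        # argmax prefers the lowest 'from' index on exact ties
        best_from = np.argmax(cand, axis=0)
        delta = cand[best_from, np.arange(spec.n_states)] + log_emis[:, obs[t]]
        back[t] = best_from
        if np.all(np.isinf(delta)):
            raise InputError(f"observation sequence impossible at frame {t}")
    path = np.empty(t_len, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    if len(observed_labels) and not isinstance(observed_labels[0], (int, np.integer)):
        return [spec.states[i] for i in path]
    return path


def path_log_probability(path, observed_labels, spec: HMMSpec) -> float:
    """Joint log probability of a state path and the observed labels."""
    obs = _observation_indices(observed_labels, spec)
    st = _observation_indices(path, spec)
    with np.errstate(divide="ignore"):
        lp = np.log(spec.initial[st[0]]) + np.log(spec.emission[st[0], obs[0]])
        for t in range(1, len(obs)):
            lp += np.log(spec.transition[st[t - 1], st[t]])
            lp += np.log(spec.emission[st[t], obs[t]])
    return float(lp)


def smooth_and_relabel(
    out: EnsembleOutput,
    threshold: float,
    spec: HMMSpec,
    background_index: int,
) -> np.ndarray:
    """IQR abstention followed by Viterbi smoothing (in that fixed order).

    The HMM state order must match the class index order of the ensemble
    output.  Returns per-frame class indices.
    """
    labels = apply_iqr_threshold(out, threshold, background_index)
    return viterbi_smooth(labels, spec)
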