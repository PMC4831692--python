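"""Autocross-covariance (ACC) featurization of PSSM profiles.

A profile's 20 column means P̄_j form the composition vector. For a lag g,
the auto-covariance (AC) term for column j is

    AC(g, j) = Σ_{i=1..L−g} (p_{i,j} − P̄_j)(p_{i+g,j} − P̄_j) / (L − g)

and the cross-covariance (CC) term for an ordered column pair (j1, j2),
j1 ≠ j2, is

    CC(g, j1, j2) = Σ_{i=1..L−g} (p_{i,j1} − P̄_{j1})(p_{i+g,j2} − P̄_{j2}) / (L − g).

With lag depth λ the AC block has 20·λ components, the CC block 380·λ, and
their concatenation F_ACC = (F_AC, F_CC) has 400·λ. Blocks are lag-major:
all components for g = 1, then g = 2, and so on; within a lag, AC follows
the canonical column order and CC runs lexicographically over ordered pairs.
The denominator is L − g (no Bessel correction) and no variance
normalization is applied: these are covariances, so features scale as the
square of the profile scale and are invariant to per-column shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mlec.pssm import CANONICAL_ALPHABET, PSSMProfile

_OFFDIAG = ~np.eye(20, dtype=bool)  # row-major scan = lexicographic (j1, j2)


@dataclass
class ACCFeatureVector:
    """The (400·λ)-dimensional ACC representation of one profile."""

    lag: int
    ac: np.ndarray
    cc: np.ndarray

    def __post_init__(self) -> None:
        self.ac = np.asarray(self.ac, dtype=float)
        self.cc = np.asarray(self.cc, dtype=float)
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.ac.shape != (20 * self.lag,):
            raise ValueError(f"AC block must have {20 * self.lag} components")
        if self.cc.shape != (380 * self.lag,):
            raise ValueError(f"CC block must have {380 * self.lag} components")

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.ac, self.cc])


def _scores(profile) -> np.ndarray:
    if isinstance(profile, PSSMProfile):
        return profile.scores
    return np.asarray(profile, dtype=float)


def _check_lag(L: int, lag: int) -> None:
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if lag >= L:
        raise ValueError(f"lag must be < profile length; got lag={lag}, L={L}")


def composition_vector(profile) -> np.ndarray:
    """Column means P̄_j of the profile — the 20-D composition vector."""
    M = _scores(profile)
    return M.mean(axis=0)


def _lag_cov(M: np.ndarray, g: int) -> np.ndarray:
    """20×20 lag-g covariance matrix of centered profile columns."""
    C = M - M.mean(axis=0)
    L = M.shape[0]
    return C[: L - g].T @ C[g:] / (L - g)


def ac_features(profile, lag: int) -> np.ndarray:
    """Auto-covariance block: 20 components per lag g = 1..lag, lag-major."""
    M = _scores(profile)
    _check_lag(M.shape[0], lag)
    return np.concatenate([np.diag(_lag_cov(M, g)) for g in range(1, lag + 1)])


def cc_features(profile, lag: int) -> np.ndarray:
    """Cross-covariance block: 380 ordered-pair components per lag, lag-major.

    Pairs run lexicographically over (j1, j2) with j1 ≠ j2, columns in
    canonical alphabetical order.
    """
    M = _scores(profile)
    _check_lag(M.shape[0], lag)
    return np.concatenate([_lag_cov(M, g)[_OFFDIAG] for g in range(1, lag + 1)])


def acc_features(profile, lag: int) -> ACCFeatureVector:
    """Full ACC vector: AC block followed by CC block, 400·lag components."""
    return ACCFeatureVector(
        lag=lag, ac=ac_features(profile, lag), cc=cc_features(profile, lag)
    )


def featurize_dataset(
    profiles: list[PSSMProfile], lag: int
) -> tuple[np.ndarray, list[str]]:
    """ACC-featurize a list of profiles into an n × 400·lag matrix.

    Row order equals input order. Profiles shorter than lag + 1 are rejected
    with the offending sequence ID.
    """
    for p in profiles:
        if p.L < lag + 1:
            raise ValueError(
                f"profile {p.sequence_id!r} too short for lag {lag} (L={p.L})"
            )
    if not profiles:
        return np.empty((0, 400 * lag)), []
    rows = [acc_features(p, lag).combined for p in profiles]
    return np.vstack(rows), [p.sequence_id for p in profiles]


def feature_names(lag: int) -> list[str]:
    """Column names matching the combined ACC layout."""
    names = []
    for g in range(1, lag + 1):
        names.extend(f"ac_g{g}_{aa}" for aa in CANONICAL_ALPHABET)
    for g in range(1, lag + 1):
        names.extend(
            f"cc_g{g}_{a1}{a2}"
            for a1 in CANONICAL_ALPHABET
            for a2 in CANONICAL_ALPHABET
            if a1 != a2
        )
    return names
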