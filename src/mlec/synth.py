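"""Seeded synthetic PSSM profiles and multi-label datasets.

The generator emulates the structure the classifier pipeline consumes: L×20
real-valued profiles whose column statistics carry class signal, annotated
with 1–3 labels per sample. Each of the m labels owns a fixed disjoint group
of ⌊20/m⌋ profile columns; an active label shifts its group's mean by
``class_shift`` on top of i.i.d. Gaussian background noise.

Because the ACC transform centers every column by its own mean, a constant
column offset alone is invisible downstream. The class offset is therefore
modulated along the sequence by a shared AR(1) latent process per active
label: position i of the group receives ``class_shift · (1 + 0.5·z_i)``
with z a stationary AR(1) series (coefficient ``ar_coeff``, unit marginal
variance) shared across the group's columns. The group's mean still shifts
by ``class_shift``, while the lag-g auto- and cross-covariances of the
group gain ``0.25 · class_shift² · ar_coeff^g`` — signal the AC/CC features
can carry. With ``class_shift = 0`` the profile is pure background noise,
indistinguishable across labels.

All randomness flows from a single integer seed: profile i uses the
generator stream seeded by (seed, i), label assignment uses a separate
stream keyed off the same seed, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from mlec.dataset import MultiLabelDataset
from mlec.features import feature_names, featurize_dataset
from mlec.pssm import CANONICAL_ALPHABET, PSSMProfile, write_ascii_pssm

_LABEL_STREAM_KEY = 999_999_937  # distinct sub-stream for label sampling


@dataclass
class SynthSpec:
    """Study conditions for the synthetic generator.

    Defaults mirror the toolkit's end-to-end test condition: 200 samples,
    six EC-like classes, unit noise, class shift of five noise standard
    deviations, and the 1–3 label cardinality mix dominated by
    single-function samples.
    """

    seed: int = 0
    n_samples: int = 200
    n_labels: int = 6
    length_range: tuple[int, int] = (50, 120)
    class_shift: float = 5.0
    label_cardinality: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.25, 3: 0.05}
    )
    noise_sd: float = 1.0
    ar_coeff: float = 0.6
    label_priors: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_labels < 2:
            raise ValueError("n_labels must be >= 2")
        if self.n_labels > 20:
            raise ValueError("n_labels > 20: not enough disjoint column groups")
        if self.class_shift < 0:
            raise ValueError("class_shift must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in [0, 1)")
        total = sum(self.label_cardinality.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("label_cardinality probabilities must sum to 1")
        if max(self.label_cardinality) > self.n_labels:
            raise ValueError("cardinality exceeds number of labels")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")


def column_groups(n_labels: int) -> list[np.ndarray]:
    """Disjoint groups of ⌊20/m⌋ canonical columns, one per label."""
    width = 20 // n_labels
    return [np.arange(j * width, (j + 1) * width) for j in range(n_labels)]


def generate_synthetic_pssm(
    spec: SynthSpec, labels: np.ndarray, index: int = 0
) -> PSSMProfile:
    """One synthetic profile for a given binary label vector.

    Deterministic given (spec.seed, index). An all-zero label vector yields
    a pure background profile.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (spec.n_labels,):
        raise ValueError(f"labels must have shape ({spec.n_labels},)")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, index]))
    lo, hi = spec.length_range
    L = int(rng.integers(lo, hi + 1))
    M = rng.normal(0.0, spec.noise_sd, size=(L, 20))
    groups = column_groups(spec.n_labels)
    active = np.flatnonzero(labels)
    rho = spec.ar_coeff
    for j in active:
        if spec.class_shift > 0:
            eps = rng.normal(0.0, 1.0, size=L)
            if rho > 0:
                # stationary AR(1) with unit marginal variance
                z0 = rng.normal()
                z, _ = lfilter(
                    [np.sqrt(1 - rho**2)], [1.0, -rho], eps, zi=np.array([rho * z0])
                )
            else:
                z = eps
            offset = spec.class_shift * (1.0 + 0.5 * z)
            M[:, groups[j]] += offset[:, None]
    residues = "".join(rng.choice(list(CANONICAL_ALPHABET), size=L))
    return PSSMProfile(
        sequence_id=f"synth{index:05d}", scores=M, residues=residues
    )


def _draw_labels(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    cards = sorted(spec.label_cardinality)
    probs = np.array([spec.label_cardinality[c] for c in cards])
    c = int(rng.choice(cards, p=probs / probs.sum()))
    priors = spec.label_priors
    if priors is not None:
        priors = np.asarray(priors, dtype=float)
        priors = priors / priors.sum()
    chosen = rng.choice(spec.n_labels, size=c, replace=False, p=priors)
    row = np.zeros(spec.n_labels, dtype=int)
    row[chosen] = 1
    return row


def generate_multilabel_dataset(
    spec: SynthSpec, lag: int = 1, return_profiles: bool = False
):
    """Generate an ACC-featurized multi-label dataset.

    Returns a :class:`MultiLabelDataset`; with ``return_profiles=True`` also
    returns the underlying profiles.
    """
    label_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _LABEL_STREAM_KEY])
    )
    Y = np.array([_draw_labels(spec, label_rng) for _ in range(spec.n_samples)])
    profiles = [
        generate_synthetic_pssm(spec, Y[i], index=i) for i in range(spec.n_samples)
    ]
    X, ids = featurize_dataset(profiles, lag)
    ds = MultiLabelDataset(
        ids=ids,
        X=X,
        Y=Y,
        feature_names=feature_names(lag),
        label_names=[f"EC{j + 1}" for j in range(spec.n_labels)],
    )
    if return_profiles:
        return ds, profiles
    return ds


def write_synth_outputs(spec: SynthSpec, out_dir, lag: int = 1) -> dict[str, str]:
    """Emit PSSM files plus features.csv / labels.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, profiles = generate_multilabel_dataset(spec, lag=lag, return_profiles=True)
    pssm_dir = out / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for p in profiles:
        (pssm_dir / f"{p.sequence_id}.pssm").write_text(write_ascii_pssm(p))
    feats = pd.DataFrame(ds.X, columns=ds.feature_names)
    feats.insert(0, "id", ds.ids)
    feats_path = out / "features.csv"
    feats.to_csv(feats_path, index=False)
    labs = pd.DataFrame(ds.Y, columns=ds.label_names)
    labs.insert(0, "id", ds.ids)
    labels_path = out / "labels.csv"
    labs.to_csv(labels_path, index=False)
    return {
        "pssm_dir": str(pssm_dir),
        "features": str(feats_path),
        "labels": str(labels_path),
    }
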