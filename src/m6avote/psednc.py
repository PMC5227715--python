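"""Pseudo dinucleotide composition (PseDNC) of RNA sequences.

A sequence of length L is summarized by its 16 dinucleotide frequencies f_k
plus lambda "pseudo" components that encode tiered physicochemical
autocorrelation along the sequence:

    theta_j = (1/(L-1-j)) * sum_{i=1}^{L-1-j} Theta(D_i, D_{i+j})

where D_i = R_i R_{i+1} is the i-th overlapping dinucleotide and the
correlation function Theta is the mean squared difference of the two
dinucleotides' standardized physicochemical property values:

    Theta(Da, Db) = (1/v) * sum_u [P_u(Da) - P_u(Db)]^2 .

The final vector of dimension 16 + lambda is

    d_k      = f_k / (1 + w * sum_j theta_j)          for k = 1..16,
    d_{16+j} = w * theta_j / (1 + w * sum_j theta_j)  for j = 1..lambda,

so all components are non-negative and sum to exactly 1. The v = 3 properties
are the nearest-neighbor thermodynamic parameters of RNA duplex formation —
enthalpy (kcal/mol), entropy (cal/(mol*K)) and free energy (kcal/mol) — which
quantify the secondary-structure propensity that disfavors methylation.
Before use each property is standardized to zero mean and unit standard
deviation over the 16 dinucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import (
    ConfigError,
    DegeneratePropertyError,
    InsufficientLengthError,
    SequenceTooShortError,
)

#: Fixed lexicographic dinucleotide order used for all 16-component vectors.
DINUCLEOTIDES = tuple(a + b for a in "ACGU" for b in "ACGU")
_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

PROPERTY_NAMES = ("enthalpy", "entropy", "free_energy")

# Nearest-neighbor thermodynamic parameters of the 16 RNA dinucleotides:
# enthalpy (kcal/mol), entropy (cal/(mol*K)), free energy (kcal/mol).
_RAW_PROPERTIES = {
    "GG": (-12.2, -29.7, -3.26),
    "GA": (-13.3, -35.5, -2.35),
    "GC": (-14.2, -34.9, -3.42),
    "GU": (-10.2, -26.2, -2.24),
    "AG": (-7.6, -19.2, -2.08),
    "AA": (-6.6, -18.4, -0.93),
    "AC": (-10.2, -26.2, -2.24),
    "AU": (-5.7, -15.5, -1.10),
    "CG": (-8.0, -19.4, -2.36),
    "CA": (-10.5, -27.8, -2.11),
    "CC": (-12.2, -29.7, -3.26),
    "CU": (-7.6, -19.2, -2.08),
    "UG": (-7.6, -19.2, -2.11),
    "UA": (-8.1, -22.6, -1.33),
    "UC": (-10.2, -26.2, -2.35),
    "UU": (-6.6, -18.4, -0.93),
}


@dataclass(frozen=True)
class PropertyTable:
    """The 16 x v matrix of dinucleotide physicochemical property values.

    ``matrix`` rows follow :data:`DINUCLEOTIDES`; columns follow
    :data:`PROPERTY_NAMES`. ``standardized`` records whether each column has
    been centered/scaled over the 16 dinucleotides.
    """

    matrix: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != 16 or m.ndim != 2:
            raise ConfigError(f"property matrix must be 16 x v, got {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def v(self) -> int:
        """Number of physicochemical properties."""
        return self.matrix.shape[1]

    def row(self, dinucleotide: str) -> np.ndarray:
        return self.matrix[_DINUC_INDEX[dinucleotide]]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("dinucleotide\t" + "\t".join(PROPERTY_NAMES[: self.v]) + "\n")
            for d, row in zip(DINUCLEOTIDES, self.matrix):
                fh.write(d + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path, standardized: bool = False) -> "PropertyTable":
        values = {}
        with open(path, "r", encoding="utf-8") as fh:
            fh.readline()  # header
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                values[parts[0]] = [float(x) for x in parts[1:]]
        missing = set(DINUCLEOTIDES) - set(values)
        if missing:
            raise ConfigError(f"property table missing rows: {sorted(missing)}")
        matrix = np.array([values[d] for d in DINUCLEOTIDES])
        return cls(matrix=matrix, standardized=standardized)


def builtin_property_table() -> PropertyTable:
    """The built-in raw enthalpy/entropy/free-energy table (v = 3)."""
    matrix = np.array([_RAW_PROPERTIES[d] for d in DINUCLEOTIDES])
    return PropertyTable(matrix=matrix, standardized=False)


def standardize_properties(table: PropertyTable) -> PropertyTable:
    """Center each property to mean 0 and scale to SD 1 over the 16 dinucleotides."""
    if table.standardized:
        return table
    mean = table.matrix.mean(axis=0)
    sd = table.matrix.std(axis=0)  # population SD over the 16 dinucleotides
    if np.any(sd == 0):
        bad = [PROPERTY_NAMES[i] for i in np.flatnonzero(sd == 0)]
        raise DegeneratePropertyError(
            f"property column(s) with zero variance cannot be standardized: {bad}"
        )
    return PropertyTable(matrix=(table.matrix - mean) / sd, standardized=True)


def theta_correlation(d1: str, d2: str, table: PropertyTable) -> float:
    """Theta(d1, d2): mean squared difference of standardized property triples.

    Symmetric, non-negative, and zero iff the two rows coincide (e.g. GG/CC
    and AC/GU, whose raw thermodynamic parameters are identical).
    """
    if not table.standardized:
        raise ConfigError("theta_correlation requires a standardized table")
    diff = table.row(d1) - table.row(d2)
    return float(np.mean(diff**2))


@dataclass(frozen=True)
class PseDncConfig:
    """PseDNC parameters: tier count ``lam`` (lambda), weight ``w`` and the
    dinucleotide counting mode for the frequency block."""

    lam: int = 6
    w: float = 0.9
    counting_mode: str = "overlapping"

    def __post_init__(self):
        if self.lam < 0:
            raise ConfigError(f"lambda must be non-negative, got {self.lam}")
        if not 0.0 <= self.w <= 1.0:
            raise ConfigError(f"w must be in [0, 1], got {self.w}")
        if self.counting_mode not in ("overlapping", "nonoverlapping"):
            raise ConfigError(f"unknown counting_mode {self.counting_mode!r}")


@dataclass(frozen=True)
class PseDncVector:
    """The (16 + lambda)-dimensional PseDNC feature vector.

    ``d`` is the full vector (sums to 1), ``f`` the 16 normalized
    dinucleotide frequencies, ``theta`` the lambda tier correlation factors.
    """

    d: np.ndarray
    f: np.ndarray
    theta: np.ndarray


def _dinuc_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int64)
    for i, c in enumerate("ACGU"):
        lut[ord(c)] = i
    codes = lut[arr]
    return codes[:-1] * 4 + codes[1:]


def dinucleotide_frequencies(seq: str, mode: str = "overlapping") -> np.ndarray:
    """The 16 normalized dinucleotide frequencies of ``seq``.

    ``overlapping`` counts all L-1 adjacent pairs; ``nonoverlapping`` counts
    pairs (1,2), (3,4), ... (an odd trailing residue is ignored).
    """
    if len(seq) < 2:
        raise SequenceTooShortError(
            f"need at least 2 residues for dinucleotide counts, got {len(seq)}"
        )
    pairs = _dinuc_codes(seq)
    if mode == "nonoverlapping":
        pairs = pairs[::2]
    elif mode != "overlapping":
        raise ConfigError(f"unknown counting mode {mode!r}")
    counts = np.bincount(pairs, minlength=16).astype(float)
    return counts / counts.sum()


def tier_correlation_factors(
    seq: str, lam: int, table: PropertyTable
) -> np.ndarray:
    """theta_1..theta_lambda: mean Theta between dinucleotides j steps apart.

    Always uses the full set of overlapping dinucleotides, independent of the
    frequency counting mode.
    """
    if not table.standardized:
        raise ConfigError("tier correlation requires a standardized table")
    L = len(seq)
    if lam > L - 2:
        raise InsufficientLengthError(L, lam)
    if lam == 0:
        return np.zeros(0)
    props = table.matrix[_dinuc_codes(seq)]  # (L-1, v)
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        diff = props[:-j] - props[j:]
        theta[j - 1] = np.mean(diff**2, axis=1).mean()
    return theta


def psednc_vector(
    seq: str, config: PseDncConfig = PseDncConfig(), table: PropertyTable | None = None
) -> PseDncVector:
    """Compute the PseDNC vector of a normalized RNA sequence."""
    if table is None:
        table = standardize_properties(builtin_property_table())
    f = dinucleotide_frequencies(seq, config.counting_mode)
    theta = tier_correlation_factors(seq, config.lam, table)
    denom = 1.0 + config.w * theta.sum()
    d = np.concatenate([f / denom, config.w * theta / denom])
    return PseDncVector(d=d, f=f, theta=theta)


def encode_psednc(
    residues: Sequence[str],
    config: PseDncConfig = PseDncConfig(),
    table: PropertyTable | None = None,
) -> np.ndarray:
    """Stack PseDNC vectors of many sequences into an (n, 16 + lambda) matrix."""
    if table is None:
        table = standardize_properties(builtin_property_table())
    return np.array([psednc_vector(s, config, table).d for s in residues])


def component_names(lam: int) -> list[str]:
    """Column names of the feature matrix: f_AA..f_UU then theta_1..theta_lam."""
    return [f"f_{d}" for d in DINUCLEOTIDES] + [f"theta_{j}" for j in range(1, lam + 1)]


def optimize_psednc_params(
    residues: Sequence[str],
    labels: Sequence[int],
    w_grid: Sequence[float] | None = None,
    lambda_grid: Sequence[int] | None = None,
    cv: int = 10,
    seed: int = 0,
) -> tuple[float, int, float]:
    """Grid-search (w, lambda) by stratified k-fold CV accuracy of an RBF SVM.

    Returns ``(best_w, best_lambda, best_cv_accuracy)``. Ties resolve to the
    first grid point in (w, lambda) iteration order.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.svm import SVC

    if w_grid is None:
        w_grid = [round(0.1 * i, 1) for i in range(1, 11)]
    if lambda_grid is None:
        lambda_grid = list(range(1, 11))
    table = standardize_properties(builtin_property_table())
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    best = (None, None, -1.0)
    for w in w_grid:
        for lam in lambda_grid:
            cfg = PseDncConfig(lam=lam, w=w)
            X = encode_psednc(residues, cfg, table)
            score = cross_val_score(SVC(kernel="rbf"), X, y, cv=skf).mean()
            if score > best[2]:
                best = (w, lam, float(score))
    return best


def replace_config(config: PseDncConfig, **kwargs) -> PseDncConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
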