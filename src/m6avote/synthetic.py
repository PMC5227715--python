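"""Synthetic labeled 51-nt window datasets with a controllable planted signal.

The generator emulates the structure of experimentally derived m6A benchmark
sets: balanced positive/negative classes of odd-length windows, each centered
on an adenosine, drawn from a background nucleotide distribution. Positives
optionally carry a planted consensus motif (default "GGACU", the canonical
methyltransferase recognition context, whose A aligns with the window center)
with probability ``plant_prob``, shifted by a small random jitter around the
center. Negatives are pure background; because background can produce the
motif by chance — as real negative windows can contain consensus-like
contexts without being methylated — negatives are not screened unless
``strict_negatives`` is set, which resamples any negative containing the
motif (useful for separability tests).

Jitter offsets that would overwrite the central adenosine with a non-A motif
letter are excluded from the candidate offsets, so every window keeps its
central A and a ``plant_prob`` of 1 guarantees the motif is present verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError
from .model import VotingScenario
from .seqio import NEGATIVE_LABEL, POSITIVE_LABEL, RnaSequence, SiteWindow, write_fasta

_NT = np.array(list("ACGU"))


@dataclass(frozen=True)
class SyntheticConfig:
    n_pos: int = 200
    n_neg: int = 200
    window_len: int = 51
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: str = "GGACU"
    plant_prob: float = 0.9
    jitter: int = 3
    strict_negatives: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.window_len % 2 != 1 or self.window_len < 1:
            raise ConfigError(f"window_len must be odd, got {self.window_len}")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ConfigError(f"background must be a probability 4-vector, got {self.background}")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ConfigError(f"plant_prob must be in [0, 1], got {self.plant_prob}")
        if set(self.motif) - set("ACGU"):
            raise ConfigError(f"motif must be over ACGU, got {self.motif!r}")
        if "A" not in self.motif:
            raise ConfigError("motif must contain an A to align with the window center")
        if self.jitter < 0:
            raise ConfigError("jitter must be non-negative")
        if not self.allowed_offsets():
            raise ConfigError("motif does not fit in the window at any allowed offset")

    @property
    def center(self) -> int:
        """0-based index of the central adenosine."""
        return self.window_len // 2

    @property
    def anchor(self) -> int:
        """0-based index of the motif letter aligned to the center at offset 0
        (the motif's first A)."""
        return self.motif.index("A")

    def allowed_offsets(self) -> list[int]:
        """Jitter shifts that keep the motif inside the window and consistent
        with the forced central A."""
        out = []
        m = len(self.motif)
        for delta in range(-self.jitter, self.jitter + 1):
            start = self.center - self.anchor + delta
            if start < 0 or start + m > self.window_len:
                continue
            covers_center = start <= self.center < start + m
            if covers_center and self.motif[self.center - start] != "A":
                continue
            out.append(delta)
        return out


def _background_window(rng: np.random.Generator, config: SyntheticConfig) -> np.ndarray:
    win = rng.choice(4, size=config.window_len, p=np.asarray(config.background))
    win[config.center] = 0  # force the central adenosine
    return win


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> list[SiteWindow]:
    """Balanced labeled windows, fully reproducible under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    offsets = config.allowed_offsets()
    motif_codes = np.array(["ACGU".index(c) for c in config.motif])
    out: list[SiteWindow] = []
    for i in range(config.n_pos):
        win = _background_window(rng, config)
        if rng.random() < config.plant_prob:
            delta = offsets[rng.integers(len(offsets))]
            start = config.center - config.anchor + delta
            win[start : start + len(motif_codes)] = motif_codes
        out.append(
            SiteWindow(
                transcript_id=f"synthetic_pos_{i + 1}",
                center_pos=config.center + 1,
                residues="".join(_NT[win]),
                label=POSITIVE_LABEL,
            )
        )
    motif = config.motif
    for i in range(config.n_neg):
        win = _background_window(rng, config)
        if config.strict_negatives:
            while motif in "".join(_NT[win]):
                win = _background_window(rng, config)
        out.append(
            SiteWindow(
                transcript_id=f"synthetic_neg_{i + 1}",
                center_pos=config.center + 1,
                residues="".join(_NT[win]),
                label=NEGATIVE_LABEL,
            )
        )
    return out


def write_dataset(
    windows: Sequence[SiteWindow], pos_path, neg_path, config: SyntheticConfig | None = None
) -> None:
    """Emit paired positive/negative FASTA files (plus a config sidecar)."""
    pos = [RnaSequence(w.transcript_id, w.residues) for w in windows if w.label == POSITIVE_LABEL]
    neg = [RnaSequence(w.transcript_id, w.residues) for w in windows if w.label == NEGATIVE_LABEL]
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    if config is not None:
        sidecar = str(pos_path) + ".config.txt"
        with open(sidecar, "w", encoding="utf-8") as fh:
            for key, value in vars(config).items():
                fh.write(f"{key} = {value}\n")


def generate_stub_votes(
    scenario: VotingScenario, truth: Sequence[str], seed: int = 0
) -> tuple[list[str], list[str], list[str]]:
    """Three label streams that independently agree with ``truth`` with
    probabilities (p1, p2, p3) — stand-in base classifiers for voting tests."""
    rng = np.random.default_rng(seed)
    streams = []
    for p in scenario.ps:
        agree = rng.random(len(truth)) < p
        stream = [
            t if ok else (NEGATIVE_LABEL if t == POSITIVE_LABEL else POSITIVE_LABEL)
            for t, ok in zip(truth, agree)
        ]
        streams.append(stream)
    return tuple(streams)
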