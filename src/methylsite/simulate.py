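"""Synthetic center-A window generator with a plantable motif signal.

The generator emulates the structure of curated methylation-site corpora:
fixed-length windows (odd length, default 101 nt) centered on an adenosine,
a configurable positive:negative ratio (1:1 for m6A-like sets, 1:10 for
m1A-like), and a fraction of windows drawn from sources shorter than the
window so the ``-`` end-padding path is exercised. Background sequence is
i.i.d. uniform over A/C/G/T; positives carry a planted consensus motif over
the center with probability ``motif_insert_prob``. The point is controlled
separability for testing the encoders and the classifier, not biological
realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .seqio import (
    GAP,
    NUCLEOTIDES,
    SequenceRecord,
    SequenceWindow,
    extract_window,
    write_fasta,
    write_labels,
)

#: default planted positive-class motif; the "A" below anchor_offset sits on
#: the window center (an m6A-consensus-like fixture, no biological claim)
DEFAULT_MOTIF = "GGACT"
DEFAULT_MOTIF_ANCHOR = 2  # 0-based offset of the center-A within the motif


@dataclass
class SyntheticSpec:
    """Study-condition knobs for one synthetic dataset.

    ``neg_per_pos`` 1 emulates the balanced m6A-style regime, 10 the
    imbalanced m1A-style regime. ``motif_insert_prob`` is the signal
    strength: 1.0 plants the motif in every positive, 0.0 makes classes
    statistically identical. ``short_seq_frac`` of windows come from
    truncated sources and therefore carry ``-`` padding.
    """

    n_pos: int = 100
    neg_per_pos: int = 10
    window_length: int = 101
    motif: str = DEFAULT_MOTIF
    motif_anchor: int = DEFAULT_MOTIF_ANCHOR
    motif_insert_prob: float = 1.0
    short_seq_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0 or self.window_length < 3:
            raise ValueError("window_length must be odd and >= 3")
        if not 0 <= self.motif_insert_prob <= 1:
            raise ValueError("motif_insert_prob must be in [0, 1]")
        if not 0 <= self.short_seq_frac <= 1:
            raise ValueError("short_seq_frac must be in [0, 1]")
        if self.n_pos < 1 or self.neg_per_pos < 0:
            raise ValueError("need n_pos >= 1 and neg_per_pos >= 0")
        if set(self.motif) - set(NUCLEOTIDES):
            raise ValueError("motif must be over A/C/G/T")
        if not 0 <= self.motif_anchor < len(self.motif):
            raise ValueError("motif_anchor outside the motif")
        if self.motif[self.motif_anchor] != "A":
            raise ValueError("the anchored motif position must be 'A'")

    @property
    def half_width(self) -> int:
        return (self.window_length - 1) // 2


def _random_source(rng: np.random.Generator, spec: SyntheticSpec,
                   short: bool) -> tuple[str, int]:
    """Draw a source sequence and the center position of its site.

    Full-length sources span the whole window; short sources are truncated
    on one or both ends (seeded choice) so extraction pads with '-'."""
    n = spec.half_width
    seq = "".join(rng.choice(list(NUCLEOTIDES), size=spec.window_length))
    center = n + 1  # 1-based
    if short:
        # drop 1..n-1 leading and/or trailing nucleotides
        mode = rng.integers(0, 3)  # 0: left, 1: right, 2: both
        cut_l = int(rng.integers(1, n)) if mode in (0, 2) and n > 1 else 0
        cut_r = int(rng.integers(1, n)) if mode in (1, 2) and n > 1 else 0
        seq = seq[cut_l: spec.window_length - cut_r]
        center -= cut_l
    # force the candidate site to be adenosine
    seq = seq[: center - 1] + "A" + seq[center:]
    return seq, center


def _plant_motif(seq: str, center: int, spec: SyntheticSpec) -> str:
    """Overwrite the motif onto the source so its anchor-A sits on the
    center; clipped to the available span."""
    start = center - 1 - spec.motif_anchor  # 0-based
    out = list(seq)
    for k, ch in enumerate(spec.motif):
        pos = start + k
        if 0 <= pos < len(out):
            out[pos] = ch
    return "".join(out)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[SequenceWindow], dict]:
    """Emit ``n_pos`` positive and ``n_pos * neg_per_pos`` negative
    labeled center-A windows, plus a provenance log.

    Positives carry the planted motif with probability
    ``motif_insert_prob``; negatives are pure background with a central A.
    Short sources (fraction ``short_seq_frac``) go through the ordinary
    window-extraction path and come out end-padded with '-'. Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_neg = spec.n_pos * spec.neg_per_pos
    labels = [1] * spec.n_pos + [0] * n_neg
    windows: list[SequenceWindow] = []
    n_planted = 0
    n_short = 0
    for idx, label in enumerate(labels):
        short = bool(rng.random() < spec.short_seq_frac)
        seq, center = _random_source(rng, spec, short)
        if label == 1 and rng.random() < spec.motif_insert_prob:
            seq = _plant_motif(seq, center, spec)
            n_planted += 1
        n_short += short
        rec = SequenceRecord(id=f"syn{idx}", sequence=seq)
        windows.append(extract_window(rec, center, spec.half_width, label=label))
    log = {
        "spec": asdict(spec),
        "n_pos": spec.n_pos,
        "n_neg": n_neg,
        "n_motif_planted": n_planted,
        "n_short_sources": int(n_short),
    }
    return windows, log


def split_dataset(
    windows: list[SequenceWindow],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[SequenceWindow], list[SequenceWindow], list[SequenceWindow]]:
    """Stratified, seeded train/validation/test partition.

    Per class, members are shuffled and cut at the cumulative fractions
    (largest-remainder rounding); every window lands in exactly one split.
    A split that would contain zero members of a present class is an error.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    splits: tuple[list, list, list] = ([], [], [])
    for label in sorted({w.label for w in windows}):
        members = [w for w in windows if w.label == label]
        order = rng.permutation(len(members))
        n = len(members)
        cuts = [int(round(fractions[0] * n)),
                int(round((fractions[0] + fractions[1]) * n))]
        parts = (order[: cuts[0]], order[cuts[0]: cuts[1]], order[cuts[1]:])
        for si, part in enumerate(parts):
            if fractions[si] > 0 and len(part) == 0:
                raise ValueError(
                    f"split {si} would contain zero members of class {label}"
                )
            splits[si].extend(members[i] for i in part)
    return splits


def save_dataset(
    windows: list[SequenceWindow], log: dict, prefix: str | Path
) -> None:
    """Write ``<prefix>.fasta``, ``<prefix>.labels.tsv`` and the JSON
    provenance sidecar ``<prefix>.json``."""
    prefix = Path(prefix)
    records = [SequenceRecord(w.window_id, w.window) for w in windows]
    write_fasta(records, str(prefix) + ".fasta")
    write_labels(windows, str(prefix) + ".labels.tsv")
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(log, fh, indent=1)
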