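"""Synthetic motif / domain-shift benchmark.

Emulates the statistical structure the adversarial method assumes: a binding
motif shared across cell types, embedded in cell-type-specific background
composition.  Backgrounds are first-order Markov (dinucleotide) chains, so
dinucleotide-shuffle negatives are non-trivial and a domain classifier has a
realistic composition signal to exploit.

The default motif is a GC-box (consensus GGGCGGGG, the binding site of
SP1-family factors).  The default source background is AT-rich with CpG
depletion; the transfer task interpolates the target background toward a
GC-rich matrix by the ``shift`` knob.  Over an AT-rich source background a
GC-rich motif makes bulk GC content a label shortcut that a source-only
classifier can latch onto — exactly the domain-specific cue that fails on a
GC-rich target and that the adversary is supposed to suppress.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequences import (
    SEQ_LEN,
    LabeledSequence,
    dinucleotide_shuffle,
    write_tsv,
)

#: alphabet order for PWM rows and transition-matrix axes
BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: moderately AT-rich background (~41% GC) with A/T stacking and CpG
#: depletion (rows: previous base A,C,G,T; columns: next base A,C,G,T).
#: Cell-type composition differences in real ChIP-seq loci are on the order
#: of a few percent GC, not wholesale alphabet swaps; the two anchors below
#: differ by ~12% GC, enough for a k-mer probe to separate domains reliably
#: over 101 bp while leaving motif features largely composition-neutral.
BG_AT_RICH = np.array(
    [
        [0.34, 0.19, 0.19, 0.28],
        [0.31, 0.22, 0.10, 0.37],
        [0.27, 0.24, 0.21, 0.28],
        [0.25, 0.19, 0.23, 0.33],
    ]
)

#: moderately GC-rich background (~53% GC, milder CpG depletion)
BG_GC_RICH = np.array(
    [
        [0.27, 0.25, 0.26, 0.22],
        [0.24, 0.29, 0.16, 0.31],
        [0.22, 0.28, 0.28, 0.22],
        [0.20, 0.26, 0.28, 0.26],
    ]
)

#: GC-box (SP1-family consensus): strongly learnable at small sample sizes,
#: and GC-rich, so bulk GC content becomes a partially label-correlated
#: shortcut over the AT-rich source background — the composition cue whose
#: usefulness degrades under the domain shift
DEFAULT_CONSENSUS = "GGGCGGGG"

#: C-run co-factor consensus: emulates a cell-type-specific partner motif
#: through which a fraction of source peaks are bound indirectly (tethered
#: binding, no canonical site).  Chosen to resemble the GC-rich target
#: background (soft-match rate ~27% per 101-mer there vs ~8% on the AT-rich
#: source background), so a classifier that leans on it misranks target
#: negatives — the non-transferable cue the adversary is meant to remove.
DEFAULT_COFACTOR_CONSENSUS = "CCCCCCCC"


@dataclass(frozen=True)
class MotifModel:
    """A position weight matrix (4 x W, rows in ACGT order) plus the
    probability that a positive sequence actually carries a planted site."""

    pwm: np.ndarray
    strength: float = 0.9

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=float)
        object.__setattr__(self, "pwm", pwm)
        if pwm.ndim != 2 or pwm.shape[0] != 4:
            raise ValueError(f"pwm must be 4 x W, got {pwm.shape}")
        if pwm.shape[1] >= SEQ_LEN:
            raise ValueError(f"motif width must be < {SEQ_LEN}")
        if not np.allclose(pwm.sum(axis=0), 1.0):
            raise ValueError("pwm columns must sum to 1")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))

    @classmethod
    def from_consensus(cls, consensus: str = DEFAULT_CONSENSUS, weight: float = 0.85,
                       strength: float = 0.9) -> "MotifModel":
        """PWM with ``weight`` on the consensus base per column and the
        remainder spread evenly over the other three bases."""
        W = len(consensus)
        pwm = np.full((4, W), (1.0 - weight) / 3.0)
        for j, b in enumerate(consensus):
            pwm[_BASE_IDX[b], j] = weight
        return cls(pwm, strength)


@dataclass(frozen=True)
class DomainSpec:
    """One cell type's synthetic data: name, background chain, sizes, seed."""

    name: str
    background: np.ndarray
    n_pos: int
    n_neg: int
    seed: int

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if bg.shape != (4, 4):
            raise ValueError(f"background must be 4x4, got {bg.shape}")
        if not np.allclose(bg.sum(axis=1), 1.0):
            raise ValueError("background transition rows must sum to 1")


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary row vector of a 4-state chain (left eigenvector at 1)."""
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _sample_background(rng: np.random.Generator, transition: np.ndarray, n: int,
                       length: int = SEQ_LEN) -> list[str]:
    """Sample n first-order Markov sequences, started from the stationary
    distribution."""
    pi = stationary_distribution(transition)
    cum_pi = np.cumsum(pi)
    cum_T = np.cumsum(transition, axis=1)
    u = rng.random((n, length))
    states = np.empty((n, length), dtype=np.int64)
    states[:, 0] = np.searchsorted(cum_pi, u[:, 0])
    for j in range(1, length):
        rows = cum_T[states[:, j - 1]]
        states[:, j] = (u[:, j:j + 1] >= rows).sum(axis=1)
    lut = np.array(list(BASES))
    return ["".join(row) for row in lut[states]]


def _plant_motif(rng: np.random.Generator, seq: str, motif: MotifModel) -> tuple[str, int]:
    """Plant one PWM draw at a uniform random position."""
    W = motif.width
    pos = int(rng.integers(0, SEQ_LEN - W + 1))
    cum = np.cumsum(motif.pwm, axis=0)
    draw = "".join(BASES[int(np.searchsorted(cum[:, j], rng.random()))] for j in range(W))
    return seq[:pos] + draw + seq[pos + W:], pos


def generate_domain(
    spec: DomainSpec,
    motif: MotifModel,
    domain_label: str = "target",
    negatives: str = "background",
    cofactor: MotifModel | None = None,
    cofactor_prob: float = 0.0,
) -> list[LabeledSequence]:
    """Generate one domain's positives and negatives.

    Positives are background 101-mers with one PWM draw planted at a uniform
    random position with probability ``motif.strength``.  Negatives are fresh
    background draws (``negatives="background"``) or dinucleotide shuffles of
    the positives (``negatives="shuffle"``).  If a ``cofactor`` motif is
    supplied, each planted positive carries the co-factor site INSTEAD of the
    binding motif with probability ``cofactor_prob`` — indirect (tethered)
    binding through a domain-specific partner; negatives are never planted.
    Pure function of the spec seed.
    """
    if negatives not in ("background", "shuffle"):
        raise ValueError("negatives must be 'background' or 'shuffle'")
    if not 0.0 <= cofactor_prob <= 1.0:
        raise ValueError("cofactor_prob must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    pos_seqs = _sample_background(rng, spec.background, spec.n_pos)
    planted = []
    for seq in pos_seqs:
        if rng.random() < motif.strength:
            indirect = cofactor is not None and rng.random() < cofactor_prob
            seq, _ = _plant_motif(rng, seq, cofactor if indirect else motif)
        planted.append(seq)
    out = [LabeledSequence(s, "positive", domain_label, origin="synthetic") for s in planted]
    if negatives == "background":
        for s in _sample_background(rng, spec.background, spec.n_neg):
            out.append(LabeledSequence(s, "negative", domain_label, origin="synthetic"))
    else:
        if spec.n_neg > spec.n_pos:
            raise ValueError("shuffle negatives require n_neg <= n_pos")
        shuffle_seeds = rng.integers(0, 2**31 - 1, size=spec.n_neg)
        for s, sd in zip(planted[: spec.n_neg], shuffle_seeds):
            out.append(LabeledSequence(dinucleotide_shuffle(s, int(sd)), "negative",
                                       domain_label, origin="shuffle"))
    return out


@dataclass
class TransferTask:
    """One target domain plus source domains sharing the motif."""

    target: list[LabeledSequence]
    sources: list[LabeledSequence]
    manifest: dict


def generate_transfer_task(
    n_domains: int = 3,
    shift: float = 1.0,
    motif: MotifModel | None = None,
    n_pos: int = 2000,
    n_neg: int = 2000,
    seed: int = 0,
    negatives: str = "background",
    confound: float = 0.0,
    cofactor: MotifModel | None = None,
    out_dir=None,
) -> TransferTask:
    """Build the cross-cell-type benchmark: labeled sources, one target.

    All domains share the binding motif.  Two domain-specific nuisances make
    transfer non-trivial:

    * composition: source backgrounds use the AT-rich matrix; the target
      background is interpolated ``(1 - shift) * AT + shift * GC``, so
      ``shift = 0`` makes all backgrounds identical and large ``shift`` gives
      the domain classifier an exploitable composition signal;
    * co-binding (optional, ``confound`` > 0): a fraction ``confound`` of the
      planted source positives carry a partner (co-factor) motif instead of
      the canonical one — indirect binding through a cell-type-specific
      partner, a label-correlated cue in the sources that does not transfer.

    If ``out_dir`` is given, writes ``target.tsv``, ``source_<i>.tsv`` and a
    ``manifest.json`` of all parameters.
    """
    if n_domains < 2:
        raise ValueError("need at least 2 domains (1 target + >= 1 source)")
    if not 0.0 <= shift <= 1.0:
        raise ValueError("shift must be in [0, 1]")
    if not 0.0 <= confound <= 1.0:
        raise ValueError("confound must be in [0, 1]")
    motif = motif or MotifModel.from_consensus()
    cofactor = cofactor or MotifModel.from_consensus(DEFAULT_COFACTOR_CONSENSUS)
    ss = np.random.SeedSequence(seed)
    domain_seeds = [int(s) for s in ss.generate_state(n_domains)]

    target_bg = (1.0 - shift) * BG_AT_RICH + shift * BG_GC_RICH
    target_spec = DomainSpec("target", target_bg, n_pos, n_neg, domain_seeds[0])
    target = generate_domain(target_spec, motif, "target", negatives)

    sources: list[LabeledSequence] = []
    for i in range(1, n_domains):
        spec = DomainSpec(f"source_{i}", BG_AT_RICH, n_pos, n_neg, domain_seeds[i])
        sources.extend(generate_domain(spec, motif, "source", negatives,
                                       cofactor=cofactor, cofactor_prob=confound))

    manifest = {
        "n_domains": n_domains,
        "shift": shift,
        "motif_consensus": motif.consensus,
        "motif_strength": motif.strength,
        "motif_pwm": motif.pwm.tolist(),
        "confound": confound,
        "cofactor_consensus": cofactor.consensus,
        "n_pos": n_pos,
        "n_neg": n_neg,
        "seed": seed,
        "negatives": negatives,
    }
    task = TransferTask(target, sources, manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tsv(target, out_dir / "target.tsv")
        for i in range(1, n_domains):
            block = [r for r in sources][(i - 1) * (n_pos + n_neg): i * (n_pos + n_neg)]
            write_tsv(block, out_dir / f"source_{i}.tsv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return task
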