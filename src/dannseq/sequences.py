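"""Sequence datasets for TF binding-site prediction.

Positive examples are 101-bp genomic windows centred on the midpoint of a
ChIP-seq peak.  Negatives are built either by dinucleotide shuffling of the
positives (composition-matched: the 16-entry dinucleotide count vector is
preserved exactly) or by sampling random genomic windows that avoid every
annotated peak.  Sequences are one-hot encoded as 4x101 matrices with the
fixed row order (T, G, C, A).

Genomes may be pyfaidx.Fasta handles or plain ``{chrom: sequence}`` dicts
(the latter is convenient for synthetic data and tests).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEQ_LEN = 101
FLANK = 50

#: one-hot row order: T -> row 0, G -> 1, C -> 2, A -> 3 (A = (0,0,0,1)^T)
ONEHOT_ROWS = "TGCA"
_ROW_OF_BASE = {b: i for i, b in enumerate(ONEHOT_ROWS)}

BINDING_LABELS = ("positive", "negative", "unknown")
DOMAIN_LABELS = ("target", "source")


@dataclass(frozen=True)
class PeakRecord:
    """A ChIP-seq peak interval in 0-based half-open (BED) coordinates."""

    chrom: str
    start: int
    end: int
    signal: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("peak chromosome name must be nonempty")
        if not self.start < self.end:
            raise ValueError(f"peak start must be < end, got [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2


@dataclass(frozen=True)
class LabeledSequence:
    """A 101-bp sequence with a binding label and a domain (cell-type) label."""

    seq: str
    binding_label: str = "unknown"
    domain_label: str = "target"
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.seq) != SEQ_LEN:
            raise ValueError(f"sequence must have length {SEQ_LEN}, got {len(self.seq)}")
        if set(self.seq) - set("ACGTN"):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(f"sequence contains characters outside ACGTN: {bad}")
        if self.binding_label not in BINDING_LABELS:
            raise ValueError(f"binding_label must be one of {BINDING_LABELS}")
        if self.domain_label not in DOMAIN_LABELS:
            raise ValueError(f"domain_label must be one of {DOMAIN_LABELS}")


# ---------------------------------------------------------------------------
# genome access (pyfaidx handle or plain dict of strings)
# ---------------------------------------------------------------------------

def _chrom_names(genome) -> list[str]:
    if isinstance(genome, Mapping):
        return list(genome.keys())
    return list(genome.keys())  # pyfaidx.Fasta also supports keys()


def _chrom_len(genome, chrom: str) -> int:
    return len(genome[chrom])


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) on the forward strand, uppercased."""
    if isinstance(genome, Mapping):
        return genome[chrom][start:end].upper()
    return str(genome[chrom][start:end]).upper()


# ---------------------------------------------------------------------------
# positive-set construction
# ---------------------------------------------------------------------------

def extract_tfbs(genome, peak: PeakRecord, domain_label: str = "target") -> LabeledSequence | None:
    """Extract the 101-bp window centred on the peak midpoint.

    The midpoint is ``start + (end - start) // 2`` in 0-based coordinates and
    the window is ``[mid - 50, mid + 51)``, so the centre base (index 50) is
    the genome base at the midpoint.

    Returns None (with a warning) when the window runs off the chromosome or
    contains an ambiguous base; raises KeyError for an unknown chromosome.
    """
    names = _chrom_names(genome)
    if peak.chrom not in names:
        raise KeyError(f"chromosome {peak.chrom!r} not present in genome (has {sorted(names)[:5]}...)")
    mid = peak.midpoint
    lo, hi = mid - FLANK, mid + FLANK + 1
    if lo < 0 or hi > _chrom_len(genome, peak.chrom):
        warnings.warn(
            f"peak {peak.chrom}:{peak.start}-{peak.end}: window [{lo},{hi}) out of bounds; skipped",
            stacklevel=2,
        )
        return None
    seq = _fetch(genome, peak.chrom, lo, hi)
    if "N" in seq:
        warnings.warn(
            f"peak {peak.chrom}:{peak.start}-{peak.end}: window contains N; skipped",
            stacklevel=2,
        )
        return None
    return LabeledSequence(seq, "positive", domain_label, origin="peak")


def extract_positive_set(genome, peaks: Iterable[PeakRecord], domain_label: str = "target") -> list[LabeledSequence]:
    """Extract all usable peak windows; logs how many peaks were dropped."""
    kept: list[LabeledSequence] = []
    dropped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for peak in peaks:
            rec = extract_tfbs(genome, peak, domain_label)
            if rec is None:
                dropped += 1
            else:
                kept.append(rec)
    logger.info("extracted %d positive windows (%d peaks dropped)", len(kept), dropped)
    return kept


# ---------------------------------------------------------------------------
# negatives
# ---------------------------------------------------------------------------

def dinucleotide_counts(seq: str) -> dict[str, int]:
    """Exhaustive count of all overlapping 2-mers."""
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


def _reaches(start: str, goal: str, last_edge: Mapping[str, str]) -> bool:
    seen = set()
    v = start
    while v != goal:
        if v in seen or v not in last_edge:
            return False
        seen.add(v)
        v = last_edge[v]
    return True


def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Eulerian-path dinucleotide shuffle (Altschul-Erikson).

    Preserves the 16-entry dinucleotide count vector exactly, hence also the
    first and last characters.  Deterministic for a given seed.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    if "N" in seq:
        raise ValueError("sequence contains N; filter N-containing sequences before shuffling")
    rng = np.random.default_rng(seed)
    first, last = seq[0], seq[-1]
    vertices = sorted(set(seq))
    if len(vertices) == 1:
        return seq
    adj: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        adj[a].append(b)

    # choose one terminal edge per non-final vertex such that terminal edges
    # form an arborescence into the final vertex (guarantees an Eulerian walk
    # that ends at `last` exists for any ordering of the remaining edges)
    movers = [v for v in vertices if v != last and adj[v]]
    while True:
        last_edge = {v: str(adj[v][rng.integers(len(adj[v]))]) for v in movers}
        if all(_reaches(v, last, last_edge) for v in movers):
            break

    walk_adj: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(adj[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        order = rng.permutation(len(edges))
        edges = [edges[i] for i in order]
        if v in last_edge:
            edges.append(last_edge[v])
        walk_adj[v] = edges

    out = [first]
    ptr = {v: 0 for v in vertices}
    v = first
    for _ in range(len(seq) - 1):
        nxt = walk_adj[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def shuffle_negatives(positives: Sequence[LabeledSequence], seed: int) -> list[LabeledSequence]:
    """One dinucleotide-shuffled negative per positive."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(positives))
    out = []
    for rec, s in zip(positives, child_seeds):
        out.append(
            LabeledSequence(
                dinucleotide_shuffle(rec.seq, int(s)),
                "negative",
                rec.domain_label,
                origin="shuffle",
            )
        )
    return out


def _admissible_start_ranges(chrom_len: int, peak_intervals: list[tuple[int, int]]):
    """Half-open ranges of window starts whose [s, s+101) avoids all peaks."""
    ranges = []
    cursor = 0
    for ps, pe in sorted(peak_intervals):
        hi = min(ps - SEQ_LEN + 1, chrom_len - SEQ_LEN + 1)
        if hi > cursor:
            ranges.append((cursor, hi))
        cursor = max(cursor, pe)
    if chrom_len - SEQ_LEN + 1 > cursor:
        ranges.append((cursor, chrom_len - SEQ_LEN + 1))
    return ranges


def sample_random_negatives(
    genome,
    peaks: Sequence[PeakRecord],
    n: int,
    seed: int,
    domain_label: str = "target",
    max_attempts_per_item: int = 200,
) -> list[LabeledSequence]:
    """Sample n random 101-bp windows that overlap no annotated peak.

    Starts are drawn uniformly over the admissible positions (the complement
    of the peak intervals, genome-wide), so saturation is detected exactly;
    windows containing N are rejected and resampled within a bounded budget.
    """
    if n == 0:
        return []
    peaks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    # flat list of (chrom, lo, hi) admissible start ranges with cumulative sizes
    ranges: list[tuple[str, int, int]] = []
    for chrom in _chrom_names(genome):
        clen = _chrom_len(genome, chrom)
        if clen < SEQ_LEN:
            continue
        for lo, hi in _admissible_start_ranges(clen, peaks_by_chrom.get(chrom, [])):
            ranges.append((chrom, lo, hi))
    total = sum(hi - lo for _, lo, hi in ranges)
    if total == 0:
        raise RuntimeError(
            f"could not place {n} non-overlapping negative windows (achieved 0): "
            "no admissible positions outside annotated peaks"
        )
    cum = np.cumsum([hi - lo for _, lo, hi in ranges])
    rng = np.random.default_rng(seed)
    out: list[LabeledSequence] = []
    attempts = 0
    budget = max_attempts_per_item * n + 1000
    while len(out) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n} non-overlapping negative windows after {attempts} attempts "
                f"(achieved {len(out)}); too many ambiguous (N) bases in the admissible regions"
            )
        attempts += 1
        flat = int(rng.integers(0, total))
        ri = int(np.searchsorted(cum, flat, side="right"))
        chrom, lo, hi = ranges[ri]
        start = lo + flat - (int(cum[ri - 1]) if ri else 0)
        seq = _fetch(genome, chrom, start, start + SEQ_LEN)
        if "N" in seq:
            continue
        out.append(LabeledSequence(seq, "negative", domain_label, origin="random-locus"))
    return out


# ---------------------------------------------------------------------------
# one-hot encoding
# ---------------------------------------------------------------------------

def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a 101-mer as a 4x101 {0,1} matrix, rows ordered (T, G, C, A).

    N encodes as an all-zero column.
    """
    if len(seq) != SEQ_LEN:
        raise ValueError(f"expected length {SEQ_LEN}, got {len(seq)}")
    mat = np.zeros((4, SEQ_LEN), dtype=np.float64)
    for j, base in enumerate(seq):
        row = _ROW_OF_BASE.get(base)
        if row is not None:
            mat[row, j] = 1.0
        elif base != "N":
            raise ValueError(f"invalid base {base!r} at position {j}")
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of one_hot_encode; all-zero columns decode to N."""
    if mat.shape != (4, SEQ_LEN):
        raise ValueError(f"expected shape (4, {SEQ_LEN}), got {mat.shape}")
    out = []
    for j in range(SEQ_LEN):
        col = mat[:, j]
        if col.sum() == 0:
            out.append("N")
        else:
            out.append(ONEHOT_ROWS[int(np.argmax(col))])
    return "".join(out)


def encode_dataset(data: Sequence[LabeledSequence], dtype=np.float32):
    """Encode a dataset to (X, binding, domain) arrays.

    binding: 0 = positive (TFBS), 1 = negative, -1 = unknown/masked.
    domain:  0 = target, 1 = source.
    """
    X = np.zeros((len(data), 4, SEQ_LEN), dtype=dtype)
    binding = np.full(len(data), -1, dtype=np.int64)
    domain = np.zeros(len(data), dtype=np.int64)
    for i, rec in enumerate(data):
        X[i] = one_hot_encode(rec.seq)
        if rec.binding_label == "positive":
            binding[i] = 0
        elif rec.binding_label == "negative":
            binding[i] = 1
        domain[i] = 0 if rec.domain_label == "target" else 1
    return X, binding, domain


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

def make_folds(data: Sequence[LabeledSequence], k: int, seed: int) -> list[np.ndarray]:
    """Partition indices into k folds, stratified by binding label.

    Shuffled per-class index blocks are dealt round-robin in one continuous
    pass, so overall fold sizes differ by at most 1 and per-class counts per
    fold differ by at most 1.
    """
    n = len(data)
    if k < 3:
        raise ValueError(f"need k >= 3 folds, got {k}")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} items")
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[int]] = {}
    for i, rec in enumerate(data):
        by_label.setdefault(rec.binding_label, []).append(i)
    folds: list[list[int]] = [[] for _ in range(k)]
    slot = 0
    for label in sorted(by_label):
        idx = np.array(by_label[label])
        rng.shuffle(idx)
        for i in idx:
            folds[slot % k].append(int(i))
            slot += 1
    return [np.array(sorted(f), dtype=np.int64) for f in folds]


def iter_fold_rotations(folds: Sequence[np.ndarray]):
    """Yield (train_idx, val_idx, test_idx) with each fold as test once.

    Rotation r uses fold r as test, fold (r+1) mod k as validation, and the
    remaining k-2 folds as training.
    """
    k = len(folds)
    for r in range(k):
        test = folds[r]
        val = folds[(r + 1) % k]
        train = np.concatenate([folds[j] for j in range(k) if j not in (r, (r + 1) % k)])
        yield np.sort(train), val, test


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_bed(path) -> list[PeakRecord]:
    """Read BED/narrowPeak/broadPeak intervals, ignoring track/comment lines.

    Extra columns beyond chrom/start/end are ignored apart from a best-effort
    signal value (narrowPeak signalValue, else the BED score column).
    """
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(parts)}")
            signal = None
            try:
                if len(parts) >= 7:
                    signal = float(parts[6])
                elif len(parts) >= 5:
                    signal = float(parts[4])
            except ValueError:
                signal = None
            peaks.append(PeakRecord(parts[0], int(parts[1]), int(parts[2]), signal))
    return peaks


def write_tsv(data: Sequence[LabeledSequence], path) -> None:
    """Write the 3-column dataset TSV (sequence, binding_label, domain_label)."""
    df = pd.DataFrame(
        {
            "sequence": [r.seq for r in data],
            "binding_label": [r.binding_label for r in data],
            "domain_label": [r.domain_label for r in data],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, origin: str = "synthetic") -> list[LabeledSequence]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sequence", "binding_label", "domain_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        LabeledSequence(row.sequence, row.binding_label, row.domain_label, origin=origin)
        for row in df.itertuples()
    ]


def write_fasta(data: Sequence[LabeledSequence], path) -> None:
    """FASTA export with labels encoded in headers."""
    with open(path, "w") as fh:
        for i, rec in enumerate(data):
            fh.write(f">seq{i} binding={rec.binding_label} domain={rec.domain_label} origin={rec.origin}\n")
            fh.write(rec.seq + "\n")
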