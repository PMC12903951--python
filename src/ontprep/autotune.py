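"""Dataset-specific cutoff self-optimization.

Every sequencing run has its own error profile, so fixed AP-identification
thresholds are either too strict or too permissive. The fit implemented here
learns, per AP end, three coupled cutoffs from the data itself:

* a similarity cutoff  s_cut  in [0.5, 1.0],
* a location cutoff    loc_cut  (maximum distance of a hit from its expected
  read terminus, in bases),
* the AP substring length  L  used for alignment.

Training data are true/random alignment pairs sampled from a subset of reads:
for each read x AP end x L, the best alignment is labelled *true* and the best
alignment avoiding the first one is labelled *random* (an AP occurs exactly
once per well-formed read, so the second-best hit is what a spurious match
looks like in this dataset). A candidate cutoff pair classifies samples as
accepted/rejected; precision measures exclusion of random alignments, recall
retention of true ones, and the cutoffs maximizing the F_beta score

    F_beta = (1 + beta^2) P R / (beta^2 P + R)

are selected — first the best (s_cut, loc_cut) per L, then the L with the
highest of those best scores. beta < 1 weights precision (F_beta -> P as
beta -> 0), beta > 1 weights recall.

The fit is exposed as :class:`AdapterCutoffModel` (built from reads or
pre-drawn samples) whose :meth:`~AdapterCutoffModel.fit` returns
:class:`CutoffFitResults` carrying the selected cutoffs, the achieved
precision/recall, the per-length diagnostic table and a ``summary()``.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import paired_hits
from .schema import APSchema, AP_IDS, end_distance
from .seqio import SequenceRecord, read_fastq

DEFAULT_BETA = 0.2  # midpoint of the precision-first 0.1-0.3 band
DEFAULT_SAMPLE_SIZE = 5000
DEFAULT_SEED = 1136
MIN_AP_SUB_LENGTH = 10

#: Candidate grids. Similarity percent 50..100 step 1; location 10..200 step
#: 10 bases; AP substring lengths from 10 to the full AP length in steps of 2
#: (full length always included).
DEFAULT_SIMILARITY_GRID = tuple(i / 100 for i in range(50, 101))
DEFAULT_LOCATION_GRID = tuple(range(10, 201, 10))

# comparisons against grid values use a tolerance well above double rounding
# noise so that s == s_cut counts as passing regardless of float representation
_EPS = 1e-9


def default_length_grid(ap_length: int) -> tuple[int, ...]:
    if ap_length < MIN_AP_SUB_LENGTH:
        return (ap_length,)
    grid = list(range(MIN_AP_SUB_LENGTH, ap_length + 1, 2))
    if grid[-1] != ap_length:
        grid.append(ap_length)
    return tuple(grid)


@dataclass(frozen=True)
class AlignmentSample:
    """One true or random alignment observation used for cutoff fitting."""

    read_id: str
    read_length: int
    ap_id: str
    ap_sub_length: int
    label: str  # "true" | "random"
    similarity: float
    end_distance: int
    strand: str


@dataclass(frozen=True)
class CutoffSet:
    """Fitted cutoffs for one AP end, with the performance they achieve."""

    ap_id: str
    similarity_cutoff: float
    location_cutoff: int
    ap_sub_length: int
    beta: float
    precision: float
    recall: float
    f_beta: float


def f_beta(P: float, R: float, beta: float) -> float:
    """Weighted harmonic mean of precision and recall."""
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    denom = beta * beta * P + R
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * P * R / denom


def evaluate_cutoff(samples: Sequence[AlignmentSample], s_cut: float,
                    loc_cut: int) -> tuple[float, float]:
    """Precision/recall of one cutoff pair on samples for a single (ap, L).

    A true sample is retained (TP) iff similarity >= s_cut and end_distance
    <= loc_cut, else it is lost (FN). A random sample counts as a false
    positive iff similarity >= s_cut, regardless of location: a spurious
    alignment that clears the similarity bar is harmful wherever it lies —
    inside the location window it becomes a false end hit, beyond it it
    becomes false chimera evidence — so only the similarity cutoff can
    exclude it. P = TP/(TP+FP) with the empty-denominator convention P = 1.
    """
    if not samples:
        raise ValueError("no samples to evaluate")
    tp = fp = fn = 0
    for sample in samples:
        sim_pass = sample.similarity >= s_cut - _EPS
        if sample.label == "true":
            if sim_pass and sample.end_distance <= loc_cut:
                tp += 1
            else:
                fn += 1
        elif sim_pass:
            fp += 1
    precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
    recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
    return precision, recall


def _reservoir_sample(reads: Iterable[SequenceRecord], k: int,
                      seed: int) -> list[SequenceRecord]:
    rng = random.Random(seed)
    reservoir: list[SequenceRecord] = []
    for i, read in enumerate(reads):
        if i < k:
            reservoir.append(read)
        else:
            j = rng.randrange(i + 1)
            if j < k:
                reservoir[j] = read
    return reservoir


def sample_alignments(reads: Iterable[SequenceRecord], schema: APSchema,
                      length_grid: Mapping[str, Sequence[int]] | Sequence[int] | None = None,
                      sample_size: int = DEFAULT_SAMPLE_SIZE,
                      seed: int = DEFAULT_SEED) -> list[AlignmentSample]:
    """Draw true/random alignment samples from up to ``sample_size`` reads.

    Reads are chosen by seeded reservoir sampling (single streaming pass).
    For each read x AP end x substring length the +/- strand first hits are
    compared and the better strand's true/random pair is recorded; reads
    shorter than a given L contribute no sample at that L.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    subset = _reservoir_sample(reads, sample_size, seed)
    if not subset:
        raise ValueError("no reads to tune on")
    grids = _resolve_length_grids(schema, length_grid)
    samples: list[AlignmentSample] = []
    for read in subset:
        n = len(read)
        for ap_id in AP_IDS:
            for L in grids[ap_id]:
                if L > n:
                    continue
                best = None  # (first, second, strand)
                for strand in ("+", "-"):
                    pattern = schema.pattern(ap_id, strand, L)
                    first, second = paired_hits(pattern, read.sequence,
                                                ap_id, strand)
                    if first is None:
                        continue
                    if best is None or first.edit_distance < best[0].edit_distance:
                        best = (first, second, strand)
                if best is None:
                    continue
                first, second, strand = best
                samples.append(AlignmentSample(
                    read_id=read.read_id, read_length=n, ap_id=ap_id,
                    ap_sub_length=L, label="true",
                    similarity=first.similarity,
                    end_distance=end_distance(ap_id, strand, first.read_start,
                                              first.read_end, n),
                    strand=strand,
                ))
                if second is not None:
                    samples.append(AlignmentSample(
                        read_id=read.read_id, read_length=n, ap_id=ap_id,
                        ap_sub_length=L, label="random",
                        similarity=second.similarity,
                        end_distance=end_distance(ap_id, strand,
                                                  second.read_start,
                                                  second.read_end, n),
                        strand=strand,
                    ))
    return samples


def _resolve_length_grids(schema: APSchema, length_grid) -> dict[str, tuple[int, ...]]:
    grids: dict[str, tuple[int, ...]] = {}
    for ap_id in AP_IDS:
        ap_len = len(schema.ap_sequence(ap_id))
        if length_grid is None:
            grids[ap_id] = default_length_grid(ap_len)
        elif isinstance(length_grid, Mapping):
            grids[ap_id] = tuple(L for L in length_grid[ap_id] if L <= ap_len)
        else:
            grids[ap_id] = tuple(L for L in length_grid if L <= ap_len)
        if not grids[ap_id]:
            raise ValueError(f"empty length grid for AP {ap_id!r}")
    return grids


def _best_cutoff_for_length(similarities: np.ndarray, distances: np.ndarray,
                            is_true: np.ndarray, beta: float,
                            s_grid: Sequence[float],
                            loc_grid: Sequence[int]):
    """Grid-search (s_cut, loc_cut) for one (ap, L); returns the best row.

    Counts for every grid cell are computed with one boolean matmul; the
    selection scan itself visits every cell, so this is an exhaustive search.
    Ties in F_beta prefer stringency: larger s_cut, then smaller loc_cut.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    loc_grid = np.asarray(loc_grid, dtype=int)
    pass_s = similarities[:, None] >= (s_grid[None, :] - _EPS)
    pass_loc = distances[:, None] <= loc_grid[None, :]
    true_s = pass_s[is_true]
    true_loc = pass_loc[is_true]
    # TP needs both cutoffs; FP (random, similarity-passing) only depends on
    # s_cut — see evaluate_cutoff for the rationale
    tp = true_s.astype(np.int64).T @ true_loc.astype(np.int64)
    fp_per_s = pass_s[~is_true].sum(axis=0).astype(np.int64)
    n_true = int(is_true.sum())
    best = None
    for i, s_cut in enumerate(s_grid):
        for j, loc_cut in enumerate(loc_grid):
            tp_ij = int(tp[i, j])
            fp_ij = int(fp_per_s[i])
            precision = 1.0 if tp_ij + fp_ij == 0 else tp_ij / (tp_ij + fp_ij)
            recall = 0.0 if n_true == 0 else tp_ij / n_true
            f = f_beta(precision, recall, beta)
            key = (f, s_cut, -loc_cut)
            if best is None or key > best[0]:
                best = (key, float(s_cut), int(loc_cut), precision, recall, f)
    return best[1:]


def optimize_cutoffs(samples: Sequence[AlignmentSample],
                     beta: float = DEFAULT_BETA,
                     s_grid: Sequence[float] = DEFAULT_SIMILARITY_GRID,
                     loc_grid: Sequence[int] = DEFAULT_LOCATION_GRID,
                     ) -> dict[str, CutoffSet]:
    """Select, per AP end, the (s_cut, loc_cut, L) maximizing F_beta.

    For each L the best (s_cut, loc_cut) is found by exhaustive grid search;
    the L whose best F_beta is highest wins. Equal-F_beta ties prefer the most
    stringent optimum: highest s_cut, then smallest loc_cut, then largest L.
    Deterministic for fixed input. Also returns nothing silently: an AP with
    no samples raises.
    """
    if f_beta(1.0, 1.0, beta) != 1.0:  # validates beta > 0
        raise AssertionError
    result: dict[str, CutoffSet] = {}
    per_ap: dict[str, list[AlignmentSample]] = {ap: [] for ap in AP_IDS}
    for sample in samples:
        per_ap.setdefault(sample.ap_id, []).append(sample)
    for ap_id in AP_IDS:
        group = per_ap.get(ap_id, [])
        if not group:
            raise ValueError(f"no alignment samples for AP {ap_id!r}")
        lengths = sorted({s.ap_sub_length for s in group})
        best = None  # ((f, s_cut, -loc, L), CutoffSet)
        for L in lengths:
            sub = [s for s in group if s.ap_sub_length == L]
            sims = np.array([s.similarity for s in sub])
            dists = np.array([s.end_distance for s in sub])
            is_true = np.array([s.label == "true" for s in sub])
            s_cut, loc_cut, precision, recall, f = _best_cutoff_for_length(
                sims, dists, is_true, beta, s_grid, loc_grid)
            key = (f, s_cut, -loc_cut, L)
            if best is None or key > best[0]:
                best = (key, CutoffSet(
                    ap_id=ap_id, similarity_cutoff=s_cut,
                    location_cutoff=loc_cut, ap_sub_length=L, beta=beta,
                    precision=precision, recall=recall, f_beta=f,
                ))
        result[ap_id] = best[1]
    return result


class AdapterCutoffModel:
    """Cutoff-selection model over true/random alignment samples.

    Build it from reads (``from_reads`` / ``from_fastq``) or directly from
    pre-drawn :class:`AlignmentSample` collections, then call :meth:`fit`.
    The sampling step is beta-independent, so one model can be fitted at
    several beta values cheaply.
    """

    def __init__(self, samples: Sequence[AlignmentSample], schema: APSchema):
        if not samples:
            raise ValueError("no alignment samples")
        self.samples = list(samples)
        self.schema = schema

    @classmethod
    def from_reads(cls, reads: Iterable[SequenceRecord], schema: APSchema,
                   sample_size: int = DEFAULT_SAMPLE_SIZE,
                   seed: int = DEFAULT_SEED,
                   length_grid=None) -> "AdapterCutoffModel":
        samples = sample_alignments(reads, schema, length_grid=length_grid,
                                    sample_size=sample_size, seed=seed)
        return cls(samples, schema)

    @classmethod
    def from_fastq(cls, path: str | Path, schema: APSchema,
                   sample_size: int = DEFAULT_SAMPLE_SIZE,
                   seed: int = DEFAULT_SEED,
                   length_grid=None) -> "AdapterCutoffModel":
        return cls.from_reads(read_fastq(path), schema,
                              sample_size=sample_size, seed=seed,
                              length_grid=length_grid)

    def fit(self, beta: float = DEFAULT_BETA,
            s_grid: Sequence[float] = DEFAULT_SIMILARITY_GRID,
            loc_grid: Sequence[int] = DEFAULT_LOCATION_GRID,
            ) -> "CutoffFitResults":
        cutoffs = optimize_cutoffs(self.samples, beta=beta, s_grid=s_grid,
                                   loc_grid=loc_grid)
        per_length = self._per_length_table(beta, s_grid, loc_grid)
        return CutoffFitResults(cutoffs=cutoffs, beta=beta, model=self,
                                per_length=per_length)

    def _per_length_table(self, beta, s_grid, loc_grid) -> pd.DataFrame:
        rows = []
        for ap_id in AP_IDS:
            group = [s for s in self.samples if s.ap_id == ap_id]
            for L in sorted({s.ap_sub_length for s in group}):
                sub = [s for s in group if s.ap_sub_length == L]
                sims = np.array([s.similarity for s in sub])
                dists = np.array([s.end_distance for s in sub])
                is_true = np.array([s.label == "true" for s in sub])
                s_cut, loc_cut, precision, recall, f = _best_cutoff_for_length(
                    sims, dists, is_true, beta, s_grid, loc_grid)
                rows.append({
                    "ap_id": ap_id, "ap_sub_length": L,
                    "similarity_cutoff": s_cut, "location_cutoff": loc_cut,
                    "precision": precision, "recall": recall, "f_beta": f,
                    "n_true": int(is_true.sum()),
                    "n_random": int((~is_true).sum()),
                })
        return pd.DataFrame(rows)


@dataclass
class CutoffFitResults:
    """Fitted cutoffs plus diagnostics.

    ``cutoffs`` maps AP end -> :class:`CutoffSet`; ``per_length`` is the
    best-F_beta-per-substring-length table behind the L selection (one row per
    AP end x L).
    """

    cutoffs: dict[str, CutoffSet]
    beta: float
    model: AdapterCutoffModel | None = None
    per_length: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            "Adapter/primer cutoff fit",
            f"  beta = {self.beta:g}   "
            f"samples = {len(self.model.samples) if self.model else 'n/a'}",
            f"  {'AP':<6}{'L':>4}{'s_cut':>8}{'loc':>6}"
            f"{'P':>8}{'R':>8}{'F_beta':>9}",
        ]
        for ap_id in AP_IDS:
            c = self.cutoffs[ap_id]
            lines.append(
                f"  {ap_id:<6}{c.ap_sub_length:>4}{c.similarity_cutoff:>8.2f}"
                f"{c.location_cutoff:>6}{c.precision:>8.4f}{c.recall:>8.4f}"
                f"{c.f_beta:>9.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "cutoffs": {ap: asdict(c) for ap, c in self.cutoffs.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @staticmethod
    def load(path: str | Path) -> "CutoffFitResults":
        data = json.loads(Path(path).read_text())
        cutoffs = {ap: CutoffSet(**c) for ap, c in data["cutoffs"].items()}
        return CutoffFitResults(cutoffs=cutoffs, beta=data["beta"])
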