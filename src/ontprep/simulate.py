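"""Ground-truthed ONT cDNA read simulator.

Reads are built from their library anatomy — front AP + insert + polyA +
revcomp(rear AP) — and then corrupted with a per-base error process mixing
substitutions, insertions and deletions, with an elevated rate within a
terminal window of each read end (nanopore translocation is least stable at
the read ends). Three read categories mirror what a real run contains:

* full_length — the intact construct;
* truncated   — sequencing stopped early: the terminal AP and polyA are gone
  along with a random suffix of the insert; the initiating-end AP survives;
* fusion      — two complete constructs concatenated (a chimera), leaving two
  AP sets with the inner ones far from the read ends.

Every emitted read carries a ground-truth row (category, strand, insert,
edit count), which is what the benchmark scores against. Identical
configurations (including the seed) produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import APSchema
from .seqio import SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}

#: Benchmark error regimes: early-chemistry raw reads (~14%), current raw
#: reads (~5%) and near-perfect basecalls (0.1%).
ERROR_RATES = (0.14, 0.05, 0.001)

#: A synthetic 25 nt AP pair used by the simulator's examples and benchmarks;
#: arbitrary fixed sequences, not any vendor's primers.
SYNTHETIC_SCHEMA = APSchema(
    kit_name="synthetic",
    front_ap="AGGTACGCTTAACGGTATCGCATCG",
    rear_ap="TCCATAGCGTTCAGACGGCATTACA",
)


def example_schema() -> APSchema:
    """The synthetic AP schema used for simulation-based benchmarking."""
    return SYNTHETIC_SCHEMA


@dataclass(frozen=True)
class SimConfig:
    """One simulated dataset: composition, error model and seed."""

    n_reads: int
    frac_full_length: float = 0.9
    frac_fusion: float = 0.0
    frac_truncated: float = 0.1
    error_rate: float = 0.05
    error_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # sub, ins, del
    insert_length_range: tuple[int, int] = (300, 2000)
    polya_length_range: tuple[int, int] = (15, 60)
    terminal_error_multiplier: float = 2.0
    terminal_window: int = 30
    clean_q: int = 20
    error_q: int = 5
    seed: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        comp = (self.frac_full_length, self.frac_fusion, self.frac_truncated)
        if any(not 0 <= f <= 1 for f in comp):
            raise ValueError(f"composition fractions outside [0,1]: {comp}")
        if abs(sum(comp) - 1) > 1e-9:
            raise ValueError(f"composition fractions must sum to 1: {comp}")
        if any(not 0 <= f <= 1 for f in self.error_mix):
            raise ValueError(f"error mix outside [0,1]: {self.error_mix}")
        if abs(sum(self.error_mix) - 1) > 1e-9:
            raise ValueError(f"error mix must sum to 1: {self.error_mix}")
        if not 0 <= self.error_rate <= 1:
            raise ValueError(f"error rate outside [0,1]: {self.error_rate}")
        for name, rng in (("insert_length_range", self.insert_length_range),
                          ("polya_length_range", self.polya_length_range)):
            if rng[0] > rng[1] or rng[0] < 1:
                raise ValueError(f"invalid {name}: {rng}")
        if self.terminal_error_multiplier < 1:
            raise ValueError("terminal_error_multiplier must be >= 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


def build_construct(insert: str, schema: APSchema, polya_len: int,
                    strand: str) -> str:
    """Clean library molecule: front + insert + polyA + rc(rear); rc on '-'."""
    construct = (schema.front_ap + insert + "A" * polya_len
                 + revcomp(schema.rear_ap))
    return construct if strand == "+" else revcomp(construct)


def make_truncated(insert: str, schema: APSchema, polya_len: int, strand: str,
                   rng: np.random.Generator) -> str:
    """Incompletely sequenced molecule.

    The sequencing-terminal AP is removed entirely, together with the polyA
    tail and a uniformly random suffix of the insert; the initiating-end AP
    stays intact. On the minus strand the as-sequenced read starts from the
    rear AP, so the front AP is the one lost.
    """
    kept = int(rng.integers(1, len(insert) + 1))
    if strand == "+":
        return schema.front_ap + insert[:kept]
    # minus-strand as-sequenced: rear + polyT + rc(insert), truncated at the end
    return schema.rear_ap + "T" * polya_len + revcomp(insert)[:kept]


def make_fusion(construct_a: str, construct_b: str) -> str:
    """Chimeric read: two complete constructs joined end to end."""
    return construct_a + construct_b


def _error_probabilities(n: int, config: SimConfig) -> np.ndarray:
    p = np.full(n, config.error_rate)
    w = min(config.terminal_window, n)
    p[:w] *= config.terminal_error_multiplier
    p[n - w:] = np.maximum(p[n - w:],
                           config.error_rate * config.terminal_error_multiplier)
    return np.minimum(p, 1.0)


def corrupt(seq: str, config: SimConfig,
            rng: np.random.Generator) -> tuple[str, list[int], int]:
    """Apply the per-base error process; returns (noisy seq, quals, n_edits).

    Each position errs with probability error_rate (doubled, by default,
    within terminal_window bases of either end); the edit type is drawn from
    error_mix. Substituted and inserted bases get ``error_q``; untouched
    bases get ``clean_q``, so per-base Phred scores track the realized local
    error process.
    """
    n = len(seq)
    if n == 0 or config.error_rate == 0:
        return seq, [config.clean_q] * n, 0
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = _error_probabilities(n, config)
    err_pos = np.nonzero(rng.random(n) < p)[0]
    if len(err_pos) == 0:
        return seq, [config.clean_q] * n, 0
    types = rng.choice(3, size=len(err_pos), p=list(config.error_mix))
    out = bytearray()
    quals: list[int] = []
    prev = 0
    n_edits = 0
    for pos, etype in zip(err_pos, types):
        seg = codes[prev:pos]
        out += seg.tobytes()
        quals.extend([config.clean_q] * len(seg))
        base = codes[pos]
        if etype == 0:  # substitution: a different base, uniform
            idx = _BASE_INDEX.get(int(base))
            if idx is None:  # N: substitute uniformly
                new = _BASES[rng.integers(4)]
            else:
                new = _BASES[(idx + int(rng.integers(1, 4))) % 4]
            out.append(int(new))
            quals.append(config.error_q)
        elif etype == 1:  # insertion before the base
            out.append(int(_BASES[rng.integers(4)]))
            quals.append(config.error_q)
            out.append(int(base))
            quals.append(config.clean_q)
        # etype == 2: deletion, emit nothing
        n_edits += 1
        prev = pos + 1
    seg = codes[prev:]
    out += seg.tobytes()
    quals.extend([config.clean_q] * len(seg))
    return out.decode(), quals, n_edits


def _allocate_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n into categories; ties by order."""
    quotas = [n * f for f in fractions]
    counts = [int(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _random_insert(rng: np.random.Generator, low: int, high: int) -> str:
    """Uniform random insert whose last 3 bases are A-free.

    The 3' terminal bases are drawn from {C,G,T} so the insert/polyA boundary
    is defined by the read itself — an insert ending in A's is inherently
    indistinguishable from the tail.
    """
    length = int(rng.integers(low, high + 1))
    body = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
    k = min(3, length)
    tail = _BASES[1 + rng.integers(0, 3, size=k)].tobytes().decode()
    return body[:length - k] + tail


def generate_dataset(config: SimConfig,
                     ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate one dataset plus its ground-truth table.

    Category counts follow largest-remainder rounding of the configured
    fractions; strands are Bernoulli(1/2); every read runs through
    :func:`corrupt`. Truth columns: read_id, category, strand, insert,
    insert_len, clean_length, n_edits.
    """
    rng = np.random.default_rng(config.seed)
    counts = _allocate_counts(
        config.n_reads,
        (config.frac_full_length, config.frac_fusion, config.frac_truncated))
    categories = (["full_length"] * counts[0] + ["fusion"] * counts[1]
                  + ["truncated"] * counts[2])
    rng.shuffle(categories)
    lo, hi = config.insert_length_range
    plo, phi = config.polya_length_range
    schema = SYNTHETIC_SCHEMA
    records: list[SequenceRecord] = []
    rows = []
    for i, category in enumerate(categories):
        read_id = f"sim_{i:06d}"
        if category == "fusion":
            parts = []
            strands = []
            inserts = []
            for _ in range(2):
                insert = _random_insert(rng, lo, hi)
                polya = int(rng.integers(plo, phi + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                parts.append(build_construct(insert, schema, polya, strand))
                strands.append(strand)
                inserts.append(insert)
            clean = make_fusion(*parts)
            strand_label = "/".join(strands)
            insert_label = ",".join(inserts)
            insert_len = sum(len(s) for s in inserts)
        else:
            insert = _random_insert(rng, lo, hi)
            polya = int(rng.integers(plo, phi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if category == "full_length":
                clean = build_construct(insert, schema, polya, strand)
            else:
                clean = make_truncated(insert, schema, polya, strand, rng)
            strand_label = strand
            insert_label = insert
            insert_len = len(insert)
        noisy, quals, n_edits = corrupt(clean, config, rng)
        records.append(SequenceRecord(read_id, noisy, quals))
        rows.append({
            "read_id": read_id, "category": category, "strand": strand_label,
            "insert": insert_label, "insert_len": insert_len,
            "clean_length": len(clean), "n_edits": n_edits,
        })
    truth = pd.DataFrame(rows)
    return records, truth


#: Default benchmark composition grid: full-length 50-100% in steps of 10,
#: fusion 0/5/10%, truncated the remainder (negative remainders dropped).
DEFAULT_FL_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
DEFAULT_FUSION_GRID = (0.0, 0.05, 0.10)


def benchmark_grid(base_config: SimConfig,
                   fl_grid: Sequence[float] = DEFAULT_FL_GRID,
                   fusion_grid: Sequence[float] = DEFAULT_FUSION_GRID,
                   error_rates: Sequence[float] = ERROR_RATES,
                   ) -> list[SimConfig]:
    """Cartesian benchmark grid of composition x error rate.

    Each config gets a distinct seed derived from the base config's seed and
    a human-readable label. The default grid yields 48 configs (16 valid
    compositions x 3 error rates).
    """
    configs = []
    idx = 0
    for fl in fl_grid:
        for fu in fusion_grid:
            tr = round(1.0 - fl - fu, 10)
            if tr < 0:
                continue
            for err in error_rates:
                seed = (base_config.seed * 100003 + idx * 7919 + 1) % (2 ** 31)
                label = f"fl{fl:.2f}_fu{fu:.2f}_err{err:g}"
                configs.append(replace(
                    base_config, frac_full_length=fl, frac_fusion=fu,
                    frac_truncated=tr, error_rate=err, seed=seed, label=label))
                idx += 1
    return configs
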