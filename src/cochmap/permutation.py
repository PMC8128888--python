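"""Two-sample permutation tests on 50% reduction times.

The statistic of interest for each frequency is the *original set difference*

    OSD = mean(control t50) - mean(operated t50)   [min]

positive when the operated ears' responses collapsed earlier (their CF places
were shifted apically).  Under the null hypothesis that operated and control
ears are draws from one distribution, group labels are exchangeable: every
re-assignment of the N+M pooled ears into pseudo-groups of sizes N and M
yields a pseudo-difference PD, and the one-sided p-value is the fraction of
assignments with PD >= OSD.  With N = 5 and M = 8 there are C(13, 5) = 1287
unique assignments, so the per-frequency test can be enumerated exactly;
Monte-Carlo permutation sampling gives the same answer to binomial accuracy
and extends to the multi-frequency grand tests, where the per-frequency PDs
are summed with either independent permutations at each frequency (method 1)
or a single shared permutation (method 2, which preserves the across-ear
correlation structure over frequency).

Ties count as exceedances (PD >= OSD), and the Monte-Carlo estimator is the
raw exceedance fraction count/n_perm; the (count+1)/(n_perm+1) variant, which
cannot return an exact zero, is available via ``estimator="plus-one"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReductionTimeTable",
    "PermutationTestResult",
    "set_difference",
    "exact_test_single",
    "mc_test_single",
    "grand_test_method1",
    "grand_test_method2",
    "run_full_inference",
    "n_exact_assignments",
    "n_grand_assignments",
]

Sided = Literal["one", "two"]
Estimator = Literal["paper", "plus-one"]

_MC_CHUNK = 200_000
_MAX_EXACT = 10_000_000


@dataclass(frozen=True)
class ReductionTimeTable:
    """Complete ears x frequencies matrix of 50% reduction times with labels."""

    ear_ids: tuple[str, ...]
    groups: tuple[str, ...]  # 'operated' | 'control' per ear
    freqs_khz: tuple[float, ...]
    t50: np.ndarray  # shape (n_ears, n_freqs), minutes

    def __post_init__(self) -> None:
        t50 = np.asarray(self.t50, dtype=float)
        object.__setattr__(self, "t50", t50)
        n_ears, n_freqs = len(self.ear_ids), len(self.freqs_khz)
        if t50.shape != (n_ears, n_freqs):
            raise ValueError(f"t50 must have shape ({n_ears}, {n_freqs})")
        if len(self.groups) != n_ears:
            raise ValueError("one group label per ear required")
        if any(g not in ("operated", "control") for g in self.groups):
            raise ValueError("groups must be 'operated' or 'control'")
        if not np.all(np.isfinite(t50)):
            raise ValueError("t50 matrix must be complete (finite) at all frequencies")
        if self.n_operated < 1 or self.n_control < 1:
            raise ValueError("need at least one ear in each group")

    @property
    def operated_mask(self) -> np.ndarray:
        return np.asarray([g == "operated" for g in self.groups])

    @property
    def n_operated(self) -> int:
        return sum(g == "operated" for g in self.groups)

    @property
    def n_control(self) -> int:
        return sum(g == "control" for g in self.groups)

    def column(self, freq_khz: float) -> np.ndarray:
        try:
            j = self.freqs_khz.index(freq_khz)
        except ValueError:
            raise KeyError(f"frequency {freq_khz} kHz not in table") from None
        return self.t50[:, j]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReductionTimeTable":
        """Build from a tidy frame with columns ear_id, group, freq_khz, t50_min."""
        wide = df.pivot(index="ear_id", columns="freq_khz", values="t50_min")
        groups = df.drop_duplicates("ear_id").set_index("ear_id")["group"]
        ear_ids = tuple(wide.index)
        return cls(
            ear_ids=ear_ids,
            groups=tuple(groups.loc[list(ear_ids)]),
            freqs_khz=tuple(float(f) for f in wide.columns),
            t50=wide.to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ear in enumerate(self.ear_ids):
            for j, f in enumerate(self.freqs_khz):
                rows.append(
                    {
                        "ear_id": ear,
                        "group": self.groups[i],
                        "freq_khz": f,
                        "t50_min": self.t50[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PermutationTestResult:
    osd: float  # observed (sum of) set difference, minutes
    n_perm: int  # permutations evaluated (C(N+M,N) for the exact test)
    exceed_count: int  # assignments with PD >= OSD (|PD| >= |OSD| two-sided)
    p: float
    method: Literal["exact", "mc_single", "mc_grand1", "mc_grand2"]
    sided: Sided
    seed: int | None = None
    freqs_khz: tuple[float, ...] = field(default_factory=tuple)
    estimator: Estimator = "paper"

    def to_dict(self) -> dict:
        return {
            "osd_min": self.osd,
            "n_perm": self.n_perm,
            "exceed_count": self.exceed_count,
            "p": self.p,
            "method": self.method,
            "sided": self.sided,
            "seed": self.seed,
            "freqs_khz": list(self.freqs_khz),
            "estimator": self.estimator,
        }


def n_exact_assignments(n_operated: int, n_control: int) -> int:
    """Number of unique pseudo-group assignments, C(N+M, N)."""
    return math.comb(n_operated + n_control, n_operated)


def n_grand_assignments(n_operated: int, n_control: int, n_freqs: int) -> int:
    """Assignments when each frequency is permuted independently: C(N+M,N)**F."""
    return n_exact_assignments(n_operated, n_control) ** n_freqs


def set_difference(table: ReductionTimeTable, freq_khz: float) -> float:
    """OSD at one frequency: mean control t50 minus mean operated t50 (min)."""
    values = table.column(freq_khz)
    op = table.operated_mask
    return float(values[~op].mean() - values[op].mean())


@lru_cache(maxsize=8)
def _combo_matrix(n_total: int, n_op: int) -> np.ndarray:
    """All C(n_total, n_op) index sets, one row per pseudo-operated assignment."""
    return np.array(list(combinations(range(n_total), n_op)), dtype=np.intp)


def _pd_from_op_sums(op_sums: np.ndarray, total: float, n_op: int, n_ctrl: int):
    """PD = mean(pseudo-control) - mean(pseudo-operated) from operated-group sums."""
    return (total - op_sums) / n_ctrl - op_sums / n_op


def _tail_count(pds: np.ndarray, osd: float, sided: Sided) -> int:
    # Ties count as exceedances.  The comparison allows ~1e-9 relative slack
    # so that floating-point summation order cannot drop an exact tie (in
    # particular the observed assignment itself); gaps between genuinely
    # distinct assignment statistics are many orders of magnitude larger.
    tol = 1e-9 * (1.0 + abs(osd))
    if sided == "one":
        return int(np.count_nonzero(pds >= osd - tol))
    return int(np.count_nonzero(np.abs(pds) >= abs(osd) - tol))


def _estimate_p(count: int, n: int, estimator: Estimator) -> float:
    if estimator == "plus-one":
        return (count + 1) / (n + 1)
    return count / n


def exact_test_single(
    table: ReductionTimeTable, freq_khz: float, sided: Sided = "one"
) -> PermutationTestResult:
    """Exact permutation test at one frequency by full enumeration.

    Every unique assignment of N of the N+M pooled ears to the pseudo-operated
    group is evaluated once, so p is an exact multiple of 1/C(N+M, N); the
    observed assignment is among them, hence p >= 1/C(N+M, N).
    """
    n_op, n_ctrl = table.n_operated, table.n_control
    n_assign = n_exact_assignments(n_op, n_ctrl)
    if n_assign > _MAX_EXACT:
        raise ValueError(
            f"C({n_op + n_ctrl},{n_op}) = {n_assign} too large to enumerate; "
            "use mc_test_single"
        )
    values = table.column(freq_khz)
    osd = set_difference(table, freq_khz)
    combos = _combo_matrix(n_op + n_ctrl, n_op)
    pds = _pd_from_op_sums(values[combos].sum(axis=1), values.sum(), n_op, n_ctrl)
    count = _tail_count(pds, osd, sided)
    return PermutationTestResult(
        osd=osd,
        n_perm=n_assign,
        exceed_count=count,
        p=count / n_assign,
        method="exact",
        sided=sided,
        freqs_khz=(freq_khz,),
    )


def _random_op_subsets(rng: np.random.Generator, n_trials: int, n_total: int, n_op: int):
    """Uniform random N-subsets of range(n_total), one per row.

    Equivalent to permuting the pooled ear list and taking the first N: the
    index set of the N smallest of n_total iid uniforms is uniform over
    subsets.
    """
    r = rng.random((n_trials, n_total))
    return np.argpartition(r, n_op - 1, axis=1)[:, :n_op]


def mc_test_single(
    table: ReductionTimeTable,
    freq_khz: float,
    n_perm: int = 100_000,
    seed: int = 0,
    sided: Sided = "one",
    estimator: Estimator = "paper",
) -> PermutationTestResult:
    """Monte-Carlo permutation test at one frequency.

    Each trial randomly permutes the pooled ear list and takes the first N as
    pseudo-operated.  The default estimator count/n_perm can return 0 when no
    sampled assignment reaches OSD; the "plus-one" estimator avoids this.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = table.column(freq_khz)
    n_op, n_ctrl = table.n_operated, table.n_control
    osd = set_difference(table, freq_khz)
    rng = np.random.default_rng(seed)
    total = values.sum()
    count = 0
    done = 0
    while done < n_perm:
        m = min(_MC_CHUNK, n_perm - done)
        subsets = _random_op_subsets(rng, m, n_op + n_ctrl, n_op)
        pds = _pd_from_op_sums(values[subsets].sum(axis=1), total, n_op, n_ctrl)
        count += _tail_count(pds, osd, sided)
        done += m
    return PermutationTestResult(
        osd=osd,
        n_perm=n_perm,
        exceed_count=count,
        p=_estimate_p(count, n_perm, estimator),
        method="mc_single",
        sided=sided,
        seed=seed,
        freqs_khz=(freq_khz,),
        estimator=estimator,
    )


def _grand_osd(table: ReductionTimeTable, freqs: Sequence[float]) -> float:
    return float(sum(set_difference(table, f) for f in freqs))


def grand_test_method1(
    table: ReductionTimeTable,
    freqs_khz: Sequence[float] | None = None,
    n_perm: int = 100_000,
    seed: int = 0,
    sided: Sided = "one",
    estimator: Estimator = "paper",
) -> PermutationTestResult:
    """Grand multi-frequency test, independent permutations per frequency.

    The observed statistic is the sum of the per-frequency OSDs; each trial
    draws an independent pseudo-grouping at every frequency and sums the
    per-frequency PDs.  Each frequency uses its own RNG stream derived from
    the master seed and the frequency value, so the result does not depend on
    the order frequencies are listed.
    """
    freqs = tuple(freqs_khz) if freqs_khz is not None else table.freqs_khz
    if len(freqs) == 0:
        raise ValueError("need at least one frequency")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_op, n_ctrl = table.n_operated, table.n_control
    n_total = n_op + n_ctrl
    osd = _grand_osd(table, freqs)
    rngs = {f: np.random.default_rng([seed, int(round(f * 1000))]) for f in freqs}
    count = 0
    done = 0
    while done < n_perm:
        m = min(_MC_CHUNK, n_perm - done)
        pd_sum = np.zeros(m)
        for f in freqs:
            values = table.column(f)
            subsets = _random_op_subsets(rngs[f], m, n_total, n_op)
            pd_sum += _pd_from_op_sums(
                values[subsets].sum(axis=1), values.sum(), n_op, n_ctrl
            )
        count += _tail_count(pd_sum, osd, sided)
        done += m
    return PermutationTestResult(
        osd=osd,
        n_perm=n_perm,
        exceed_count=count,
        p=_estimate_p(count, n_perm, estimator),
        method="mc_grand1",
        sided=sided,
        seed=seed,
        freqs_khz=freqs,
        estimator=estimator,
    )


def grand_test_method2(
    table: ReductionTimeTable,
    freqs_khz: Sequence[float] | None = None,
    n_perm: int = 100_000,
    seed: int = 0,
    sided: Sided = "one",
    estimator: Estimator = "paper",
) -> PermutationTestResult:
    """Grand multi-frequency test, one shared permutation across frequencies.

    The same pseudo-grouping is applied at every frequency before summing the
    PDs, which is equivalent to a single-frequency test on the per-ear sums of
    t50 across frequencies.  Because real ears vary coherently across
    frequency, this preserves that correlation under the null and is the more
    conservative of the two grand methods on such data.
    """
    freqs = tuple(freqs_khz) if freqs_khz is not None else table.freqs_khz
    if len(freqs) == 0:
        raise ValueError("need at least one frequency")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_op, n_ctrl = table.n_operated, table.n_control
    cols = np.column_stack([table.column(f) for f in freqs])
    row_sums = cols.sum(axis=1)
    osd = _grand_osd(table, freqs)
    rng = np.random.default_rng(seed)
    total = row_sums.sum()
    count = 0
    done = 0
    while done < n_perm:
        m = min(_MC_CHUNK, n_perm - done)
        subsets = _random_op_subsets(rng, m, n_op + n_ctrl, n_op)
        pds = _pd_from_op_sums(row_sums[subsets].sum(axis=1), total, n_op, n_ctrl)
        count += _tail_count(pds, osd, sided)
        done += m
    return PermutationTestResult(
        osd=osd,
        n_perm=n_perm,
        exceed_count=count,
        p=_estimate_p(count, n_perm, estimator),
        method="mc_grand2",
        sided=sided,
        seed=seed,
        freqs_khz=freqs,
        estimator=estimator,
    )


def run_full_inference(
    table: ReductionTimeTable,
    n_perm: int = 100_000,
    seed: int = 0,
    estimator: Estimator = "paper",
    include_exact: bool = True,
) -> dict:
    """Per-frequency exact and Monte-Carlo tests plus both grand methods.

    Returns a JSON-serializable report with one- and two-sided p-values,
    seeds and permutation counts for every test run.
    """
    report: dict = {
        "meta": {
            "n_operated": table.n_operated,
            "n_control": table.n_control,
            "freqs_khz": list(table.freqs_khz),
            "n_perm": n_perm,
            "seed": seed,
            "estimator": estimator,
            "n_exact_assignments": n_exact_assignments(
                table.n_operated, table.n_control
            ),
            "n_grand_assignments_independent": n_grand_assignments(
                table.n_operated, table.n_control, len(table.freqs_khz)
            ),
        },
        "per_freq": [],
    }
    for f in table.freqs_khz:
        entry: dict = {"freq_khz": f, "osd_min": set_difference(table, f)}
        if include_exact:
            entry["exact"] = {
                s: exact_test_single(table, f, sided=s).to_dict() for s in ("one", "two")
            }
        entry["mc"] = {
            s: mc_test_single(
                table, f, n_perm=n_perm, seed=seed, sided=s, estimator=estimator
            ).to_dict()
            for s in ("one", "two")
        }
        report["per_freq"].append(entry)
    report["grand_method1"] = {
        s: grand_test_method1(
            table, n_perm=n_perm, seed=seed, sided=s, estimator=estimator
        ).to_dict()
        for s in ("one", "two")
    }
    report["grand_method2"] = {
        s: grand_test_method2(
            table, n_perm=n_perm, seed=seed, sided=s, estimator=estimator
        ).to_dict()
        for s in ("one", "two")
    }
    return report
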