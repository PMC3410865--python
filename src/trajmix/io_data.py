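"""Count tables, taxonomy, perturbation schedules and derived offsets.

Input conventions
-----------------
Counts are TSV files with refOTU identifiers in the first column and
observation days (real numbers) as the remaining column labels; cells are
non-negative integer sequencing counts.  An optional reserved row with id
``_total_reads`` carries the total reads per sample (which may exceed the
column sum because low-abundance refOTUs were dropped upstream); when absent,
totals default to the column sums.  Taxonomy is a TSV with columns
``refotu, order, family, genus`` (missing labels become ``unclassified``).
A perturbation schedule is a YAML mapping of the five study intervals
``a``–``e`` (pre-antibiotic, pulse 1, post-1, pulse 2, post-2) to
``[start, end)`` day pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import DataError

TOTALS_ROW_ID = "_total_reads"
INTERVALS = ("a", "b", "c", "d", "e")
RANKS = ("order", "family", "genus")


@dataclass(frozen=True)
class PerturbationSchedule:
    """Five contiguous half-open day intervals [start, end) named a..e.

    Intervals b and d are the two antibiotic pulses and must have positive
    length; the whole study range is [a.start, e.end).
    """

    boundaries: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        b = tuple((float(s), float(e)) for s, e in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        if len(b) != 5:
            raise DataError(f"schedule needs 5 intervals, got {len(b)}")
        for name, (s, e) in zip(INTERVALS, b):
            if not e > s and name in ("b", "d"):
                raise DataError(f"antibiotic interval {name} must have positive length")
            if e < s:
                raise DataError(f"interval {name} has end {e} < start {s}")
        for i in range(4):
            if b[i][1] != b[i + 1][0]:
                raise DataError(
                    f"intervals {INTERVALS[i]} and {INTERVALS[i+1]} are not contiguous"
                )

    @property
    def start(self) -> float:
        return self.boundaries[0][0]

    @property
    def end(self) -> float:
        return self.boundaries[4][1]

    @property
    def knots(self) -> np.ndarray:
        """The six boundary days (a0, b0, c0, d0, e0, e1)."""
        return np.array([iv[0] for iv in self.boundaries] + [self.end])

    def interval_of(self, t: float) -> int:
        """Index 0..4 of the interval containing day ``t``.

        The final boundary is included (closed at the study end).
        """
        if t < self.start or t > self.end:
            raise DataError(f"day {t} outside study range [{self.start}, {self.end}]")
        if t == self.end:
            return 4
        for i, (s, e) in enumerate(self.boundaries):
            if s <= t < e:
                return i
        raise DataError(f"day {t} not covered by schedule")  # pragma: no cover

    def interval_indices(self, times: np.ndarray) -> np.ndarray:
        return np.array([self.interval_of(t) for t in np.asarray(times, float)])


@dataclass
class CountsDataset:
    """Per-subject refOTU-by-time count matrices with taxonomy and totals.

    ``counts[s]`` is an (O_s, T_s) integer array aligned with ``refotus[s]``
    rows and ``times[s]`` columns; ``totals[s]`` are per-sample total read
    counts.  Irregular sampling is first-class: each subject has its own
    strictly increasing day grid.
    """

    subjects: list[str]
    counts: dict[str, np.ndarray]
    times: dict[str, np.ndarray]
    refotus: dict[str, list[str]]
    taxonomy: dict[str, dict[str, str]] = field(default_factory=dict)
    totals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.subjects:
            y = np.asarray(self.counts[s])
            if not np.issubdtype(y.dtype, np.integer):
                if not np.all(y == np.floor(y)):
                    raise DataError(f"subject {s}: non-integer counts")
                y = y.astype(np.int64)
            if (y < 0).any():
                raise DataError(f"subject {s}: negative counts")
            self.counts[s] = y
            t = np.asarray(self.times[s], float)
            if len(t) != y.shape[1]:
                raise DataError(f"subject {s}: {len(t)} times for {y.shape[1]} columns")
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise DataError(f"subject {s}: observation days not strictly increasing")
            self.times[s] = t
            if len(self.refotus[s]) != y.shape[0]:
                raise DataError(f"subject {s}: refOTU ids do not match matrix rows")
            if s not in self.totals or self.totals[s] is None:
                self.totals[s] = y.sum(axis=0).astype(np.int64)
            tot = np.asarray(self.totals[s], np.int64)
            if (tot <= 0).any():
                raise DataError(f"subject {s}: non-positive total reads")
            if (tot < y.sum(axis=0)).any():
                raise DataError(f"subject {s}: totals below column sums")
            self.totals[s] = tot
            for o in self.refotus[s]:
                self.taxonomy.setdefault(
                    o, {r: "unclassified" for r in RANKS}
                )

    @property
    def n_refotus(self) -> dict[str, int]:
        return {s: self.counts[s].shape[0] for s in self.subjects}

    def units(self) -> list[tuple[str, str]]:
        """All (subject, refOTU) pairs in deterministic order."""
        return [(s, o) for s in self.subjects for o in self.refotus[s]]


# ---------------------------------------------------------------------------
# readers / writers


def load_schedule(path) -> PerturbationSchedule:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        bounds = tuple((float(raw[k][0]), float(raw[k][1])) for k in INTERVALS)
    except (KeyError, TypeError, IndexError) as exc:
        raise DataError(f"schedule file {path}: needs keys a..e -> [start, end]") from exc
    return PerturbationSchedule(bounds)


def write_schedule(schedule: PerturbationSchedule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: [float(s), float(e)] for k, (s, e) in zip(INTERVALS, schedule.boundaries)},
            fh,
            sort_keys=False,
        )


def load_taxonomy(path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "refotu" not in cols:
        raise DataError(f"taxonomy file {path}: missing 'refotu' column")
    tax: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        labels = {}
        for r in RANKS:
            v = row[cols[r]] if r in cols else None
            labels[r] = "unclassified" if v is None or pd.isna(v) or v == "" else str(v)
        tax[str(row[cols["refotu"]])] = labels
    return tax


def write_taxonomy(taxonomy: dict[str, dict[str, str]], path) -> None:
    rows = [{"refotu": o, **labels} for o, labels in taxonomy.items()]
    pd.DataFrame(rows, columns=["refotu", *RANKS]).to_csv(path, sep="\t", index=False)


def load_counts_table(
    path, taxonomy_path=None, schedule_path=None, subject: str = "S1"
) -> tuple[CountsDataset, PerturbationSchedule | None]:
    """Load one subject's count table (plus taxonomy and schedule if given).

    Returns the dataset and the schedule (``None`` when no schedule path was
    supplied).  Malformed rows are rejected with row-level diagnostics.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    try:
        raw_days = [float(c) for c in header]
    except ValueError as exc:
        raise DataError(f"{path}: column labels must be observation days") from exc
    if len(set(raw_days)) != len(raw_days):
        raise DataError(f"{path}: duplicate time columns")
    df = pd.read_csv(path, sep="\t", index_col=0)
    days = np.array(raw_days)
    order = np.argsort(days)
    df = df.iloc[:, order]
    days = days[order]

    totals = None
    if TOTALS_ROW_ID in df.index:
        totals = df.loc[TOTALS_ROW_ID].to_numpy()
        df = df.drop(index=TOTALS_ROW_ID)
    bad = []
    for rid, row in df.iterrows():
        vals = row.to_numpy()
        if np.any(pd.isna(vals)) or not np.all(vals == np.floor(vals.astype(float))):
            bad.append(str(rid))
    if bad:
        raise DataError(f"{path}: non-integer or missing counts in rows: {', '.join(bad)}")
    counts = df.to_numpy().astype(np.int64)
    taxonomy = load_taxonomy(taxonomy_path) if taxonomy_path else {}
    ds = CountsDataset(
        subjects=[subject],
        counts={subject: counts},
        times={subject: days},
        refotus={subject: [str(i) for i in df.index]},
        taxonomy=taxonomy,
        totals={subject: totals} if totals is not None else {},
    )
    schedule = load_schedule(schedule_path) if schedule_path else None
    return ds, schedule


def write_counts_table(dataset: CountsDataset, subject: str, path) -> None:
    df = pd.DataFrame(
        dataset.counts[subject],
        index=pd.Index(dataset.refotus[subject], name="refotu"),
        columns=[format(t, "g") for t in dataset.times[subject]],
    )
    totals = pd.DataFrame(
        [dataset.totals[subject]], index=pd.Index([TOTALS_ROW_ID], name="refotu"),
        columns=df.columns,
    )
    pd.concat([df, totals]).to_csv(path, sep="\t")


def concat_datasets(datasets: list[CountsDataset]) -> CountsDataset:
    """Merge single-subject datasets into one multi-subject dataset."""
    out = CountsDataset(subjects=[], counts={}, times={}, refotus={}, taxonomy={}, totals={})
    for ds in datasets:
        for s in ds.subjects:
            if s in out.subjects:
                raise DataError(f"duplicate subject {s}")
            out.subjects.append(s)
            out.counts[s] = ds.counts[s]
            out.times[s] = ds.times[s]
            out.refotus[s] = list(ds.refotus[s])
            out.totals[s] = ds.totals[s]
        out.taxonomy.update(ds.taxonomy)
    return out


# ---------------------------------------------------------------------------
# operations


def filter_refotus(
    dataset: CountsDataset, min_count: int = 5, min_timepoints: int = 10
) -> CountsDataset:
    """Keep refOTUs detected at >= ``min_count`` counts on >= ``min_timepoints`` days.

    The filter is applied per subject: refOTU ``o`` survives in subject ``s``
    iff ``#{t : y_sot >= min_count} >= min_timepoints``.  Idempotent; row
    order within each subject is preserved.
    """
    counts, refotus, totals, times = {}, {}, {}, {}
    for s in dataset.subjects:
        y = dataset.counts[s]
        keep = (y >= min_count).sum(axis=1) >= min_timepoints
        counts[s] = y[keep]
        refotus[s] = [o for o, k in zip(dataset.refotus[s], keep) if k]
        totals[s] = dataset.totals[s]
        times[s] = dataset.times[s]
    return CountsDataset(
        subjects=list(dataset.subjects),
        counts=counts,
        times=times,
        refotus=refotus,
        taxonomy=dict(dataset.taxonomy),
        totals=totals,
    )


def compute_read_depth_offsets(dataset: CountsDataset) -> dict[str, np.ndarray]:
    """Centered log total-read offsets phi_st = log N_st - mean_t log N_st.

    exp(phi_s,t1 - phi_s,t2) equals the total-read ratio N_s,t1 / N_s,t2, so
    the offsets absorb sequencing-depth differences among samples without
    shifting the overall amplitude scale of a subject.
    """
    phi = {}
    for s in dataset.subjects:
        tot = np.asarray(dataset.totals[s], float)
        if (tot <= 0).any():
            raise DataError(f"subject {s}: zero total reads at a sample")
        lt = np.log(tot)
        phi[s] = lt - lt.mean()
    return phi


def map_to_common_timescale(
    schedule_s: PerturbationSchedule, schedule_ref: PerturbationSchedule, t
) -> float | np.ndarray:
    """Piecewise-linear monotone map sending subject days onto a reference scale.

    The six interval boundaries of ``schedule_s`` are mapped exactly onto
    those of ``schedule_ref``; days in between are linearly interpolated.
    This places experiments with different perturbation timing on a common
    time-scale for simultaneous analysis.
    """
    t_arr = np.asarray(t, float)
    if np.any(t_arr < schedule_s.start) or np.any(t_arr > schedule_s.end):
        raise DataError(
            f"day(s) outside study range [{schedule_s.start}, {schedule_s.end}]"
        )
    out = np.interp(t_arr, schedule_s.knots, schedule_ref.knots)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def restrict_to_days(dataset: CountsDataset, days: dict[str, np.ndarray]) -> CountsDataset:
    """Subset each subject's columns to the given observation days."""
    counts, times, totals = {}, {}, {}
    for s in dataset.subjects:
        want = np.asarray(days[s], float)
        idx = []
        for d in want:
            j = np.where(np.isclose(dataset.times[s], d))[0]
            if len(j) == 0:
                raise DataError(f"subject {s}: day {d} not observed")
            idx.append(int(j[0]))
        idx = sorted(set(idx))
        counts[s] = dataset.counts[s][:, idx]
        times[s] = dataset.times[s][idx]
        totals[s] = dataset.totals[s][idx]
    return CountsDataset(
        subjects=list(dataset.subjects),
        counts=counts,
        times=times,
        refotus={s: list(dataset.refotus[s]) for s in dataset.subjects},
        taxonomy=dict(dataset.taxonomy),
        totals=totals,
    )
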