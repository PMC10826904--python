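"""Domain types and delimited-text I/O for nCounter expression data.

An nCounter run reports one nonnegative integer count per sample x probe
cell.  Probes fall into four classes: positive controls carry a known
spiked-in RNA amount (in fM) and anchor the count-vs-RNA regression;
negative controls have no target and measure background binding;
housekeeping genes are assumed stably expressed; regular genes are the
targets of interest.  All modelling happens on the log10 scale.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeClass",
    "ProbeAnnotation",
    "NCounterDataset",
    "MetaStudyCollection",
    "PriorSpec",
    "META_ANALYTIC_PRIOR",
    "DEFAULT_PSEUDOCOUNT",
    "default_positive_levels",
    "log_transform",
    "read_counts_table",
    "write_counts_table",
    "read_meta_collection",
]

#: Pseudo-count added before the log10 transform so zero counts stay finite.
DEFAULT_PSEUDOCOUNT = 1.0

#: Spike-in RNA amounts (fM) of the six standard positive control probes,
#: highest to lowest.
DEFAULT_POSITIVE_FM = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


class ProbeClass(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    HOUSEKEEPING = "housekeeping"
    REGULAR = "regular"


#: Canonical probe-class ordering used for all internal matrix layouts.
CLASS_ORDER = (
    ProbeClass.POSITIVE,
    ProbeClass.NEGATIVE,
    ProbeClass.HOUSEKEEPING,
    ProbeClass.REGULAR,
)


@dataclass(frozen=True)
class ProbeAnnotation:
    """One probe's identity, class and (for positive probes) RNA amount."""

    probe_id: str
    probe_class: ProbeClass
    rna_level_fM: float | None = None

    def __post_init__(self) -> None:
        if self.probe_class is ProbeClass.POSITIVE:
            if self.rna_level_fM is None:
                raise ValueError(
                    f"positive probe {self.probe_id!r} lacks an RNA level (fM)"
                )
            if not (self.rna_level_fM > 0):
                raise ValueError(
                    f"positive probe {self.probe_id!r} has non-positive RNA level"
                )
        elif self.rna_level_fM is not None:
            raise ValueError(
                f"probe {self.probe_id!r} of class {self.probe_class.value} "
                "must not carry an RNA level"
            )


def default_positive_levels() -> np.ndarray:
    """log10 RNA levels of the six standard positive probes (descending)."""
    return np.log10(np.asarray(DEFAULT_POSITIVE_FM))


def _order_annotation(annotation: list[ProbeAnnotation]) -> list[int]:
    """Permutation grouping probes by class in canonical order.

    Within a class the original (file) order is preserved.
    """
    rank = {cls: k for k, cls in enumerate(CLASS_ORDER)}
    return sorted(range(len(annotation)), key=lambda j: rank[annotation[j].probe_class])


@dataclass
class NCounterDataset:
    """One study's counts matrix plus probe annotation.

    ``counts`` is samples x probes with probes grouped by class:
    positive, negative, housekeeping, regular.  Dimension bookkeeping
    follows the (I, P, N, H, R) convention.
    """

    counts: np.ndarray
    sample_ids: list[str]
    annotation: list[ProbeAnnotation]
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x probes matrix")
        I, J = self.counts.shape
        if len(self.sample_ids) != I:
            raise ValueError("sample_ids length does not match counts rows")
        if len(self.annotation) != J:
            raise ValueError("annotation length does not match counts columns")
        if len(set(self.sample_ids)) != I:
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
        ids = [a.probe_id for a in self.annotation]
        if len(set(ids)) != J:
            dupes = {p for p in ids if ids.count(p) > 1}
            raise ValueError(f"duplicate probe ids: {sorted(dupes)}")
        self._validate_counts()
        # enforce canonical class grouping
        perm = _order_annotation(self.annotation)
        if perm != list(range(J)):
            self.annotation = [self.annotation[j] for j in perm]
            self.counts = self.counts[:, perm]
        self.counts = self.counts.astype(np.int64)
        if self.dims[1] < 3:
            raise ValueError(
                "at least 3 positive probes are required for identifiable "
                f"positive-control regressions (got {self.dims[1]})"
            )
        lv = self.positive_levels_fM
        if len(set(lv.tolist())) != len(lv):
            raise ValueError("positive-probe RNA levels must be distinct")

    def _validate_counts(self) -> None:
        arr = self.counts
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        bad = ~np.isfinite(arr.astype(float))
        bad |= arr.astype(float) < 0
        bad |= arr.astype(float) != np.round(arr.astype(float))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "counts must be finite nonnegative integers; offending cell "
                f"sample {self.sample_ids[i]!r} x probe "
                f"{self.annotation[j].probe_id!r} = {arr[i, j]!r}"
            )

    # -- dimension bookkeeping -------------------------------------------
    @property
    def dims(self) -> tuple[int, int, int, int, int]:
        """(I, P, N, H, R): samples and probe counts per class."""
        I = self.counts.shape[0]
        by = {cls: 0 for cls in CLASS_ORDER}
        for a in self.annotation:
            by[a.probe_class] += 1
        return (I, by[ProbeClass.POSITIVE], by[ProbeClass.NEGATIVE],
                by[ProbeClass.HOUSEKEEPING], by[ProbeClass.REGULAR])

    def class_slice(self, cls: ProbeClass) -> slice:
        """Column slice of ``counts`` holding probes of class ``cls``."""
        _, P, N, H, R = self.dims
        width = {ProbeClass.POSITIVE: P, ProbeClass.NEGATIVE: N,
                 ProbeClass.HOUSEKEEPING: H, ProbeClass.REGULAR: R}
        start = 0
        for c in CLASS_ORDER:
            if c is cls:
                return slice(start, start + width[c])
            start += width[c]
        raise KeyError(cls)

    def probe_ids(self, cls: ProbeClass | None = None) -> list[str]:
        if cls is None:
            return [a.probe_id for a in self.annotation]
        sl = self.class_slice(cls)
        return [a.probe_id for a in self.annotation[sl]]

    @property
    def positive_levels_fM(self) -> np.ndarray:
        sl = self.class_slice(ProbeClass.POSITIVE)
        return np.asarray([a.rna_level_fM for a in self.annotation[sl]], dtype=float)

    @property
    def positive_levels_log10(self) -> np.ndarray:
        """X+ : known log10 RNA levels of the positive probes."""
        return np.log10(self.positive_levels_fM)

    def counts_for(self, cls: ProbeClass) -> np.ndarray:
        return self.counts[:, self.class_slice(cls)]


def log_transform(dataset: NCounterDataset | np.ndarray,
                  pseudocount: float | None = None) -> np.ndarray:
    """Y = log10(count + pseudocount), elementwise.

    The pseudo-count (default 1) keeps the transform total on zero counts,
    which occur routinely on negative probes.
    """
    if isinstance(dataset, NCounterDataset):
        pc = dataset.pseudocount if pseudocount is None else pseudocount
        arr = dataset.counts
    else:
        pc = DEFAULT_PSEUDOCOUNT if pseudocount is None else pseudocount
        arr = np.asarray(dataset)
    return np.log10(arr.astype(float) + pc)


@dataclass(frozen=True)
class PriorSpec:
    """Normal priors for the global intercept/slope means, plus the shared
    inverse-gamma and safe-range settings used by the samplers.

    ``mu_a_prior`` / ``mu_b_prior`` are (mean, variance) pairs.  The default
    instance :data:`META_ANALYTIC_PRIOR` carries the meta-analytic values
    mu_a ~ N(2.357, 0.041), mu_b ~ N(0.952, 0.003).
    """

    mu_a_prior: tuple[float, float] = (2.357, 0.041)
    mu_b_prior: tuple[float, float] = (0.952, 0.003)
    ig_epsilon: float = 0.01
    safe_range_halfwidth_sd: float = 5.0

    def __post_init__(self) -> None:
        if not (self.mu_a_prior[1] > 0 and self.mu_b_prior[1] > 0):
            raise ValueError("prior variances must be strictly positive")
        if not (self.ig_epsilon > 0):
            raise ValueError("ig_epsilon must be positive")


#: Default priors from the multi-study meta-analysis of positive-probe data.
META_ANALYTIC_PRIOR = PriorSpec()


@dataclass
class MetaStudyCollection:
    """K studies of positive-probe log10 counts sharing one design vector.

    Each study is (study_id, logY) with logY of shape I_k x 6; ``x_levels``
    is the shared 6-vector of log10 spike-in amounts X+.
    """

    studies: list[tuple[str, np.ndarray]]
    x_levels: np.ndarray = field(default_factory=default_positive_levels)

    def __post_init__(self) -> None:
        self.x_levels = np.asarray(self.x_levels, dtype=float)
        J = self.x_levels.size
        clean = []
        for sid, logY in self.studies:
            logY = np.asarray(logY, dtype=float)
            if logY.ndim != 2 or logY.shape[1] != J:
                raise ValueError(
                    f"study {sid!r}: expected I_k x {J} log-count matrix, "
                    f"got shape {logY.shape}"
                )
            if logY.shape[0] < 2:
                raise ValueError(f"study {sid!r} has fewer than 2 samples")
            if not np.isfinite(logY).all():
                raise ValueError(f"study {sid!r} contains non-finite log counts")
            clean.append((sid, logY))
        self.studies = clean

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def sizes(self) -> list[int]:
        return [logY.shape[0] for _, logY in self.studies]


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def read_annotation(path) -> list[ProbeAnnotation]:
    """Read a probe annotation CSV with columns probe_id, class, rna_level_fM."""
    df = pd.read_csv(path, dtype={"probe_id": str, "class": str})
    required = {"probe_id", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file {path} must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        try:
            cls = ProbeClass(str(row["class"]).strip().lower())
        except ValueError:
            raise ValueError(
                f"probe {row['probe_id']!r}: unknown probe class {row['class']!r}"
            ) from None
        level = row.get("rna_level_fM")
        if level is None or (isinstance(level, float) and math.isnan(level)):
            level = None
        else:
            level = float(level)
        out.append(ProbeAnnotation(str(row["probe_id"]), cls, level))
    return out


def read_counts_table(path, annotation_path,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> NCounterDataset:
    """Read a counts CSV (first column sample id, header of probe ids) and
    its annotation CSV into a validated :class:`NCounterDataset`."""
    annotation = read_annotation(annotation_path)
    with open(path) as fh:
        header = next(csv.reader(fh))[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate probe columns in {path}: {dupes}")
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample rows in {path}: {dupes}")
    ann_ids = [a.probe_id for a in annotation]
    missing = set(df.columns) - set(ann_ids)
    if missing:
        raise ValueError(f"probes without annotation (missing class): {sorted(missing)}")
    absent = set(ann_ids) - set(df.columns)
    if absent:
        raise ValueError(f"annotated probes absent from counts table: {sorted(absent)}")
    # align columns to annotation order; NCounterDataset regroups by class
    df = df[ann_ids]
    return NCounterDataset(
        counts=df.to_numpy(),
        sample_ids=[str(s) for s in df.index],
        annotation=annotation,
        pseudocount=pseudocount,
    )


def write_counts_table(dataset: NCounterDataset, path, annotation_path=None) -> None:
    """Write the counts matrix (and optionally the annotation) back to CSV."""
    df = pd.DataFrame(dataset.counts, index=dataset.sample_ids,
                      columns=dataset.probe_ids())
    df.index.name = "sample_id"
    df.to_csv(path)
    if annotation_path is not None:
        rows = [
            {"probe_id": a.probe_id, "class": a.probe_class.value,
             "rna_level_fM": a.rna_level_fM if a.rna_level_fM is not None else ""}
            for a in dataset.annotation
        ]
        pd.DataFrame(rows).to_csv(annotation_path, index=False)


def read_meta_collection(study_paths: dict, x_levels_path=None) -> MetaStudyCollection:
    """Assemble a :class:`MetaStudyCollection` from per-study CSVs of
    positive-probe log10 counts (samples x 6, first column sample id).

    ``x_levels_path`` is a one-column CSV of log10 fM levels; when omitted,
    the six standard levels are assumed.
    """
    if x_levels_path is not None:
        x = pd.read_csv(x_levels_path, header=None).to_numpy(dtype=float).ravel()
    else:
        x = default_positive_levels()
    studies = []
    for sid, p in study_paths.items():
        df = pd.read_csv(p, index_col=0)
        studies.append((str(sid), df.to_numpy(dtype=float)))
    return MetaStudyCollection(studies=studies, x_levels=x)
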