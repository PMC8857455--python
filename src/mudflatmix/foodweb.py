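"""Food-web and consumer isotope tables: reading, pooling, screening.

Dietary sources for staging shorebirds arrive as per-study summary rows
(n, mean +/- SD of delta13C and delta15N, elemental C:N), typically compiled
from several field campaigns at the same site.  This module validates those
tables, pools replicate studies of one source into a single dietary endpoint,
and screens consumer tissue samples for individuals whose strongly depleted
delta13C signals terrestrial (upland) rather than intertidal feeding.

Units: delta13C is reported in per mil vs VPDB, delta15N in per mil vs AIR.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from mudflatmix.errors import FormatError, ValidationError

TISSUES = frozenset({"liver", "muscle", "adipose", "breath", "diet"})

#: Default liver/muscle screening threshold (per mil).  Individuals with
#: delta13C below this are treated as carrying a terrestrial dietary signal;
#: marine-feeding cohort means at the study site all sit above it.
DEFAULT_TERRESTRIAL_THRESHOLD = -19.0

_D13C_RANGE = (-40.0, 0.0)
_D15N_RANGE = (-5.0, 25.0)


@dataclass(frozen=True)
class IsotopeSample:
    """A single tissue (or breath) isotope measurement of one individual."""

    sample_id: str
    species: str
    tissue: str
    d13C: float
    d15N: float | None = None
    collection_date: _dt.date | None = None
    site: str = ""

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"unknown tissue {self.tissue!r}; expected one of {sorted(TISSUES)}"
            )
        if not _D13C_RANGE[0] <= self.d13C <= _D13C_RANGE[1]:
            raise ValidationError(
                f"sample {self.sample_id}: d13C={self.d13C} outside {_D13C_RANGE}"
            )
        if self.d15N is not None and not _D15N_RANGE[0] <= self.d15N <= _D15N_RANGE[1]:
            raise ValidationError(
                f"sample {self.sample_id}: d15N={self.d15N} outside {_D15N_RANGE}"
            )


@dataclass(frozen=True)
class SourceSummary:
    """Per-study summary statistics for one dietary source.

    ``sd_d13C``/``sd_d15N`` may be ``None`` when the study reported too few
    replicates (n < 3) to publish a dispersion.
    """

    source_name: str
    study_label: str
    n: int
    mean_d13C: float
    sd_d13C: float | None
    mean_d15N: float | None
    sd_d15N: float | None
    cn_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"{self.source_name}: n must be >= 1, got {self.n}")
        for name in ("sd_d13C", "sd_d15N"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{self.source_name}: {name} must be >= 0")
        if self.cn_ratio is not None and self.cn_ratio <= 0:
            raise ValidationError(f"{self.source_name}: cn_ratio must be > 0")


@dataclass(frozen=True)
class PooledEndpoint:
    """A dietary endpoint pooled across the studies of one source."""

    source_name: str
    n_total: int
    mean_d13C: float
    sd_d13C: float | None
    mean_d15N: float | None
    sd_d15N: float | None
    cn_ratio: float | None = None


@dataclass(frozen=True)
class ScreenResult:
    """Partition of consumer samples into marine-feeding and terrestrial."""

    retained: tuple[IsotopeSample, ...]
    flagged_terrestrial: tuple[IsotopeSample, ...]
    threshold_d13C: float


def _pool_moment(
    ns: Sequence[int],
    means: Sequence[float],
    sds: Sequence[float | None],
) -> tuple[float, float | None]:
    """Pool per-group (n, mean, sd) into a combined mean and sd.

    Uses the exact two-moment combination: the total sum of squares is the
    within-group part, sum (n_i - 1) s_i^2, plus the between-group part,
    sum n_i (xbar_i - xbar)^2.  Groups whose sd was never reported contribute
    only the between-group term.  The combined sd divides by N - 1 so that a
    single group passes through unchanged.
    """
    n_total = sum(ns)
    grand = sum(n * m for n, m in zip(ns, means)) / n_total
    if n_total < 2:
        return grand, sds[0] if len(sds) == 1 else None
    ss = 0.0
    any_sd = False
    for n, m, s in zip(ns, means, sds):
        if s is not None:
            ss += (n - 1) * s * s
            any_sd = True
        ss += n * (m - grand) ** 2
    if not any_sd and len(ns) == 1:
        return grand, None
    return grand, math.sqrt(ss / (n_total - 1))


def pool_endpoints(summaries: Sequence[SourceSummary]) -> PooledEndpoint:
    """Pool the per-study summaries of one dietary source into an endpoint.

    The pooled mean of each isotope is the n-weighted mean of the group
    means; the pooled sd combines within-group variance with the dispersion
    of group means around the pooled mean (see :func:`_pool_moment`).
    Total n is conserved and the result does not depend on input order.

    Raises
    ------
    ValidationError
        If ``summaries`` is empty or mixes different ``source_name`` values.
    """
    if not summaries:
        raise ValidationError("cannot pool an empty list of summaries")
    names = {s.source_name for s in summaries}
    if len(names) > 1:
        raise ValidationError(f"cannot pool mixed sources: {sorted(names)}")
    if len(summaries) == 1:
        s = summaries[0]
        return PooledEndpoint(
            source_name=s.source_name,
            n_total=s.n,
            mean_d13C=s.mean_d13C,
            sd_d13C=s.sd_d13C,
            mean_d15N=s.mean_d15N,
            sd_d15N=s.sd_d15N,
            cn_ratio=s.cn_ratio,
        )

    # canonical order makes the floating-point result permutation-invariant
    summaries = sorted(summaries, key=lambda s: (s.study_label, s.n, s.mean_d13C))
    ns = [s.n for s in summaries]
    mean_c, sd_c = _pool_moment(ns, [s.mean_d13C for s in summaries], [s.sd_d13C for s in summaries])
    if all(s.mean_d15N is not None for s in summaries):
        mean_n, sd_n = _pool_moment(
            ns, [s.mean_d15N for s in summaries], [s.sd_d15N for s in summaries]
        )
    else:
        mean_n, sd_n = None, None
    cns = {s.cn_ratio for s in summaries if s.cn_ratio is not None}
    return PooledEndpoint(
        source_name=summaries[0].source_name,
        n_total=sum(ns),
        mean_d13C=mean_c,
        sd_d13C=sd_c,
        mean_d15N=mean_n,
        sd_d15N=sd_n,
        cn_ratio=cns.pop() if len(cns) == 1 else None,
    )


def screen_terrestrial(
    samples: Iterable[IsotopeSample],
    threshold_d13C: float = DEFAULT_TERRESTRIAL_THRESHOLD,
) -> ScreenResult:
    """Partition consumer samples by the terrestrial-feeding delta13C screen.

    A sample is flagged when its delta13C lies strictly below the threshold;
    samples exactly at the threshold are retained.  Input order is preserved
    in both partitions and every input sample appears in exactly one.
    """
    retained: list[IsotopeSample] = []
    flagged: list[IsotopeSample] = []
    for s in samples:
        (flagged if s.d13C < threshold_d13C else retained).append(s)
    return ScreenResult(
        retained=tuple(retained),
        flagged_terrestrial=tuple(flagged),
        threshold_d13C=threshold_d13C,
    )


# ---------------------------------------------------------------------------
# CSV plumbing

FOODWEB_COLUMNS = ["source", "study", "n", "mean_d13C", "sd_d13C", "mean_d15N", "sd_d15N", "cn_ratio"]
SAMPLE_COLUMNS = ["sample_id", "species", "tissue", "date", "site", "d13C", "d15N"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def _opt_float(value, path: Path, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(f"{path}, row {row}: non-numeric {column}={value!r}") from None


def read_food_web(path: str | Path) -> list[SourceSummary]:
    """Read a food-web summary table (``foodweb.csv`` dialect).

    Columns: ``source,study,n,mean_d13C,sd_d13C,mean_d15N,sd_d15N,cn_ratio``;
    empty cells mark missing sds / C:N.  Malformed rows are reported with
    their (1-based, header-inclusive) line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(df, FOODWEB_COLUMNS, path)
    out: list[SourceSummary] = []
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        try:
            n = int(rec["n"])
        except ValueError:
            raise FormatError(f"{path}, row {line}: non-integer n={rec['n']!r}") from None
        mean_c = _opt_float(rec["mean_d13C"], path, line, "mean_d13C")
        if mean_c is None:
            raise FormatError(f"{path}, row {line}: missing mean_d13C")
        try:
            out.append(
                SourceSummary(
                    source_name=rec["source"],
                    study_label=rec["study"],
                    n=n,
                    mean_d13C=mean_c,
                    sd_d13C=_opt_float(rec["sd_d13C"], path, line, "sd_d13C"),
                    mean_d15N=_opt_float(rec["mean_d15N"], path, line, "mean_d15N"),
                    sd_d15N=_opt_float(rec["sd_d15N"], path, line, "sd_d15N"),
                    cn_ratio=_opt_float(rec["cn_ratio"], path, line, "cn_ratio"),
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{path}, row {line}: {exc}") from exc
    return out


def read_samples(path: str | Path) -> list[IsotopeSample]:
    """Read individual isotope samples (``samples.csv`` dialect).

    Columns: ``sample_id,species,tissue,date,site,d13C,d15N``; d15N may be
    empty (adipose, breath).  Duplicate sample ids are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(df, SAMPLE_COLUMNS, path)
    out: list[IsotopeSample] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2
        d13c = _opt_float(rec["d13C"], path, line, "d13C")
        if d13c is None:
            raise FormatError(f"{path}, row {line}: missing d13C")
        date = None
        if rec["date"]:
            try:
                date = _dt.date.fromisoformat(rec["date"])
            except ValueError:
                raise FormatError(
                    f"{path}, row {line}: date {rec['date']!r} is not ISO formatted"
                ) from None
        if rec["sample_id"] in seen:
            raise FormatError(f"{path}, row {line}: duplicate sample_id {rec['sample_id']!r}")
        seen.add(rec["sample_id"])
        try:
            out.append(
                IsotopeSample(
                    sample_id=rec["sample_id"],
                    species=rec["species"],
                    tissue=rec["tissue"],
                    d13C=d13c,
                    d15N=_opt_float(rec["d15N"], path, line, "d15N"),
                    collection_date=date,
                    site=rec["site"],
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{path}, row {line}: {exc}") from exc
    return out


def write_food_web(summaries: Iterable[SourceSummary], path: str | Path) -> None:
    """Write summaries back in the ``foodweb.csv`` dialect (round-trippable)."""
    rows = [
        {
            "source": s.source_name,
            "study": s.study_label,
            "n": s.n,
            "mean_d13C": s.mean_d13C,
            "sd_d13C": s.sd_d13C,
            "mean_d15N": s.mean_d15N,
            "sd_d15N": s.sd_d15N,
            "cn_ratio": s.cn_ratio,
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=FOODWEB_COLUMNS).to_csv(path, index=False)


def write_samples(samples: Iterable[IsotopeSample], path: str | Path) -> None:
    """Write samples back in the ``samples.csv`` dialect (round-trippable)."""
    rows = [
        {
            "sample_id": s.sample_id,
            "species": s.species,
            "tissue": s.tissue,
            "date": s.collection_date.isoformat() if s.collection_date else "",
            "site": s.site,
            "d13C": s.d13C,
            "d15N": s.d15N,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, index=False)


def write_endpoints(endpoints: Iterable[PooledEndpoint], path: str | Path) -> None:
    """Write pooled endpoints as CSV (per mil, VPDB/AIR conventions)."""
    rows = [
        {
            "source": e.source_name,
            "n_total": e.n_total,
            "mean_d13C": e.mean_d13C,
            "sd_d13C": e.sd_d13C,
            "mean_d15N": e.mean_d15N,
            "sd_d15N": e.sd_d15N,
            "cn_ratio": e.cn_ratio,
        }
        for e in endpoints
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
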