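"""Reading and writing matched-cohort survival data, plus packaged fixtures.

The canonical on-disk format is a long CSV, one row per subject, with
columns ``pair_id, exposure, time, event`` (extra columns are carried
through).  A wide pair-per-row format with columns
``pair_id, x1, y1, x0, y0`` is also accepted.  Lines starting with ``#``
are comments; writers embed the generating configuration and seed there.
"""

from __future__ import annotations

import math
from io import StringIO
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .errors import PairingError, ValidationError
from .pair_data import PairCounts, PairRecord, pair_type_table
from .coxph import SubjectRow

__all__ = [
    "read_long_csv",
    "read_long_frame",
    "read_wide_csv",
    "write_long_csv",
    "write_pair_type_csv",
    "pairs_to_frame",
    "fixture_cohort",
    "FIXTURE_NAMES",
]

LONG_COLUMNS = ("pair_id", "exposure", "time", "event")
WIDE_COLUMNS = ("pair_id", "x1", "y1", "x0", "y0")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ValidationError(f"cannot read CSV {path!r}: {exc}") from exc


def read_long_frame(path) -> pd.DataFrame:
    """Read and validate a long-format CSV into a tidy frame."""
    df = _read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"long CSV must have columns {list(LONG_COLUMNS)}; missing {missing}"
        )
    bad_lines = []
    exposure = pd.to_numeric(df["exposure"], errors="coerce")
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    for i in df.index:
        if (
            exposure[i] not in (0, 1)
            or event[i] not in (0, 1)
            or not (time[i] > 0)
            or not math.isfinite(time[i])
        ):
            bad_lines.append(int(i) + 2)  # 1-based, after the header line
    if bad_lines:
        raise ValidationError(
            f"malformed rows (need exposure/event in {{0,1}}, time > 0) "
            f"at lines {bad_lines[:20]}"
        )
    df = df.copy()
    df["exposure"] = exposure.astype(int)
    df["time"] = time.astype(float)
    df["event"] = event.astype(int)
    return df


def _frame_to_pairs(df: pd.DataFrame) -> list[PairRecord]:
    pairs = []
    bad = []
    for pid, grp in df.groupby("pair_id", sort=False):
        if len(grp) != 2 or sorted(grp["exposure"]) != [0, 1]:
            bad.append(pid)
            continue
        e = grp[grp["exposure"] == 1].iloc[0]
        u = grp[grp["exposure"] == 0].iloc[0]
        pairs.append(PairRecord(pid, float(e["time"]), int(e["event"]),
                                float(u["time"]), int(u["event"])))
    if bad:
        raise PairingError(
            f"pairs must have exactly one exposed and one unexposed member; "
            f"offending pair ids: {bad[:20]}"
        )
    return pairs


def read_long_csv(
    path, pair_view: bool = False
) -> Union[list[SubjectRow], list[PairRecord]]:
    """Read a long CSV as subject rows, or as matched pairs (``pair_view``)."""
    df = read_long_frame(path)
    if pair_view:
        return _frame_to_pairs(df)
    return [
        SubjectRow(
            subject_id=(row.pair_id, int(row.exposure)),
            time=float(row.time),
            event=int(row.event),
            covariates=(float(row.exposure),),
            cluster_id=row.pair_id,
            stratum=row.pair_id,
        )
        for row in df.itertuples(index=False)
    ]


def read_wide_csv(path) -> list[PairRecord]:
    """Read the wide pair-per-row format (pair_id, x1, y1, x0, y0)."""
    df = _read_csv(path)
    missing = [c for c in WIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"wide CSV must have columns {list(WIDE_COLUMNS)}; missing {missing}"
        )
    pairs = []
    for row in df.itertuples(index=False):
        p = PairRecord(row.pair_id, float(row.x1), int(row.y1),
                       float(row.x0), int(row.y0))
        p.validate()
        pairs.append(p)
    return pairs


def pairs_to_frame(pairs: Iterable[PairRecord]) -> pd.DataFrame:
    """Long-format frame of a pair cohort (two rows per pair)."""
    records = []
    for p in pairs:
        records.append({"pair_id": p.pair_id, "exposure": 1,
                        "time": p.x1, "event": p.y1})
        records.append({"pair_id": p.pair_id, "exposure": 0,
                        "time": p.x0, "event": p.y0})
    return pd.DataFrame(records, columns=list(LONG_COLUMNS))


def write_long_csv(
    pairs: Iterable[PairRecord],
    path,
    header_comment: Optional[str] = None,
) -> None:
    """Write a pair cohort as long CSV, with an optional ``#`` header."""
    df = pairs_to_frame(pairs)
    buf = StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def write_pair_type_csv(
    counts: PairCounts, path, header_comment: Optional[str] = None
) -> None:
    """Write the pair-type frequency table (plus G, H) as CSV."""
    df = pair_type_table(counts)
    buf = StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    buf.write(f"# G = {counts.G}, H = {counts.H}, "
              f"comparable = {counts.n_comparable}, total = {counts.n_total}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# packaged fixtures (generated deterministically; no data files shipped)

FIXTURE_NAMES = ("one_per_type", "rotterdam_counts")
_FIXTURE_TAU = 10.0


def _one_per_type() -> list[PairRecord]:
    spec = [
        # (x1, y1, x0, y0) — one pair of each of the nine types, tau = 10
        (1.0, 1, 2.0, 1),   # 1
        (2.0, 1, 1.0, 1),   # 2
        (1.0, 1, 2.0, 0),   # 3
        (2.0, 0, 1.0, 1),   # 4
        (1.0, 0, 2.0, 1),   # 5
        (2.0, 1, 1.0, 0),   # 6
        (1.0, 0, 2.0, 0),   # 7
        (2.0, 0, 1.0, 0),   # 8
        (10.0, 0, 10.0, 0),  # 9 (both administratively censored at tau)
    ]
    return [PairRecord(f"P{i+1}", *s) for i, s in enumerate(spec)]


def _rotterdam_counts() -> list[PairRecord]:
    """A synthetic 446-pair cohort tabulating to G = 198, H = 135.

    Emulates the published pair counts of the propensity-matched breast
    cancer cohort at the level of its sufficient statistics only; the times
    are synthetic.  Type split: n1=120, n2=80, n3=78, n4=55, n5=30, n6=30,
    n7=20, n8=15, n9=18 (G = n1+n3 = 198, H = n2+n4 = 135).
    """
    rng = np.random.default_rng(20170605)
    counts = {1: 120, 2: 80, 3: 78, 4: 55, 5: 30, 6: 30, 7: 20, 8: 15, 9: 18}
    pairs = []
    k = 0
    for code, n in counts.items():
        for _ in range(n):
            a, b = np.sort(rng.uniform(0.5, _FIXTURE_TAU - 0.5, size=2))
            a, b = float(a), float(b)
            if code == 1:
                rec = (a, 1, b, 1)
            elif code == 2:
                rec = (b, 1, a, 1)
            elif code == 3:
                rec = (a, 1, b, 0)
            elif code == 4:
                rec = (b, 0, a, 1)
            elif code == 5:
                rec = (a, 0, b, 1)
            elif code == 6:
                rec = (b, 1, a, 0)
            elif code == 7:
                rec = (a, 0, b, 0)
            elif code == 8:
                rec = (b, 0, a, 0)
            else:
                rec = (_FIXTURE_TAU, 0, _FIXTURE_TAU, 0)
            pairs.append(PairRecord(f"R{k}", *rec))
            k += 1
    return pairs


def fixture_cohort(name: str) -> tuple[list[PairRecord], float]:
    """Return a packaged deterministic cohort and its tau.

    ``'one_per_type'`` is the nine-pair cohort with one pair of each type;
    ``'rotterdam_counts'`` is a synthetic cohort whose pair counts match the
    published propensity-matched breast-cancer cohort (G=198, H=135).
    """
    if name == "one_per_type":
        return _one_per_type(), _FIXTURE_TAU
    if name == "rotterdam_counts":
        return _rotterdam_counts(), _FIXTURE_TAU
    raise ValidationError(
        f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}"
    )
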