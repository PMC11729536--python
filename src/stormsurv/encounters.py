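"""Encounter histories, Pradel splitting, and m-array construction.

An encounter history is a binary vector over breeding-season occasions
(1 = individual seen/captured).  The sufficient statistic for CJS-type models
is the m-array: ``m[i, j]`` counts releases at occasion *i* next detected at
occasion *j*.  For trap-dependent models, histories are first split at every
detection ("Pradel splitting"), so each detection before the final occasion
opens a new release; the resulting m-array rows condition on the individual
having just been seen, which is exactly the state the trap-dependent
resighting structure needs.

Occasions are 1-based in every user-facing structure and report.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EncounterHistory",
    "OccasionIndex",
    "ReleaseSegment",
    "MArray",
    "read_capture_histories",
    "summarize",
    "split_histories",
    "build_marray",
    "histories_to_matrix",
    "matrix_to_histories",
    "write_marray",
    "read_marray",
]


class FormatError(ValueError):
    """Malformed input file (ragged rows, non-binary symbols, bad dialect)."""


@dataclass(frozen=True)
class EncounterHistory:
    """One marked individual's 0/1 detection record over all occasions."""

    individual_id: str
    detections: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.detections:
            raise ValueError(f"history {self.individual_id!r}: empty detections")
        if any(d not in (0, 1) for d in self.detections):
            raise ValueError(
                f"history {self.individual_id!r}: entries must be 0/1"
            )
        if sum(self.detections) == 0:
            raise ValueError(
                f"history {self.individual_id!r}: all-zero history (never detected)"
            )

    @property
    def first_occasion(self) -> int:
        """1-based index of the first detection."""
        return self.detections.index(1) + 1

    @property
    def n_occasions(self) -> int:
        return len(self.detections)

    @property
    def n_detections(self) -> int:
        return int(sum(self.detections))


@dataclass(frozen=True)
class OccasionIndex:
    """Calendar labels for occasions; occasion k <-> breeding season years[k-1]."""

    years: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.years) < 2:
            raise ValueError("need at least two occasions")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")

    @property
    def n_occasions(self) -> int:
        return len(self.years)

    @property
    def n_intervals(self) -> int:
        return len(self.years) - 1

    def winter_labels(self) -> list[str]:
        """Label survival interval t as the winter between seasons t and t+1."""
        return [f"{a}/{str(b)[-2:]}" for a, b in zip(self.years, self.years[1:])]


@dataclass(frozen=True)
class ReleaseSegment:
    """One Pradel-split release: detected at ``release_occasion``,
    next detected at ``next_detection`` (1-based) or never (None)."""

    individual_id: str
    release_occasion: int
    next_detection: int | None


@dataclass
class MArray:
    """Release-cohort summary: R_i releases, m_ij next-recapture counts.

    ``next_recapture[i-1, j-1]`` is m_ij (1-based occasions); rows for the
    final occasion are structurally zero (no information after study end).
    """

    n_occasions: int
    releases: np.ndarray          # shape (n_occasions,), int
    next_recapture: np.ndarray    # shape (n_occasions, n_occasions), int
    occasions: OccasionIndex | None = None

    def __post_init__(self) -> None:
        self.releases = np.asarray(self.releases, dtype=int)
        self.next_recapture = np.asarray(self.next_recapture, dtype=int)
        n = self.n_occasions
        if self.releases.shape != (n,):
            raise ValueError("releases must have length n_occasions")
        if self.next_recapture.shape != (n, n):
            raise ValueError("next_recapture must be (n_occasions, n_occasions)")
        if (self.next_recapture < 0).any() or (self.releases < 0).any():
            raise ValueError("counts must be non-negative")
        if np.tril(self.next_recapture).any():
            raise ValueError("m_ij must be zero for j <= i")
        row_sums = self.next_recapture.sum(axis=1)
        if (row_sums > self.releases).any():
            raise ValueError("sum_j m_ij exceeds R_i")

    @property
    def never_again(self) -> np.ndarray:
        return self.releases - self.next_recapture.sum(axis=1)

    @property
    def total_releases(self) -> int:
        return int(self.releases.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MArray):
            return NotImplemented
        return (
            self.n_occasions == other.n_occasions
            and np.array_equal(self.releases, other.releases)
            and np.array_equal(self.next_recapture, other.next_recapture)
        )


# ---------------------------------------------------------------------------
# readers

_INP_COMMENT = re.compile(r"/\*(.*?)\*/")


def _read_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str) and "\n" not in source:
        try:
            if Path(source).is_file():
                return Path(source).read_text()
        except OSError:
            pass
    if isinstance(source, io.IOBase):
        return source.read()
    return str(source)


def _parse_matrix_csv(text: str) -> list[EncounterHistory]:
    histories: list[EncounterHistory] = []
    width: int | None = None
    rows = [ln.strip() for ln in text.splitlines() if ln.strip()]
    header_skipped = False
    for lineno, line in enumerate(rows, start=1):
        fields = [f.strip() for f in line.split(",")] if "," in line else [line]
        ident: str | None = None
        if fields and not all(_is_binary_field(f) for f in fields):
            # allow one leading id column, or a header row (contains a word
            # such as "id"; year-label headers need that leading column too)
            has_word = any(any(ch.isalpha() for ch in f) for f in fields)
            if all(_is_binary_field(f) for f in fields[1:]) and len(fields) > 1:
                ident, fields = fields[0], fields[1:]
            elif lineno == 1 and not header_skipped and has_word and len(fields) > 1:
                header_skipped = True
                continue
            else:
                bad = next(f for f in fields if not _is_binary_field(f))
                raise FormatError(f"row {lineno}: non-binary symbol {bad!r}")
        dets: list[int] = []
        for f in fields:
            if len(f) > 1:  # undelimited digit string like "101"
                dets.extend(int(c) for c in f)
            else:
                dets.append(int(f))
        if width is None:
            width = len(dets)
        elif len(dets) != width:
            raise FormatError(f"row {lineno}: ragged row ({len(dets)} != {width})")
        if sum(dets) == 0:
            raise FormatError(f"row {lineno}: all-zero history")
        histories.append(
            EncounterHistory(ident or f"ind{len(histories) + 1}", tuple(dets))
        )
    if not histories:
        raise FormatError("no histories found")
    return histories


def _is_binary_field(f: str) -> bool:
    return bool(f) and set(f) <= {"0", "1"}


def _parse_mark_inp(text: str) -> list[EncounterHistory]:
    histories: list[EncounterHistory] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _INP_COMMENT.search(line)
        ident = m.group(1).strip() if m else None
        line = _INP_COMMENT.sub(" ", line)
        line = line.rstrip(";").strip()
        if not line:
            continue
        parts = line.split()
        if not parts:
            continue
        hist = parts[0]
        freq = 1
        if len(parts) >= 2:
            try:
                freq = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad frequency {parts[1]!r}") from exc
        if not _is_binary_field(hist):
            raise FormatError(f"line {lineno}: non-binary symbol in {hist!r}")
        dets = tuple(int(c) for c in hist)
        if sum(dets) == 0:
            raise FormatError(f"line {lineno}: all-zero history")
        for k in range(freq):
            label = ident if (ident and freq == 1) else (
                f"{ident or f'line{lineno}'}#{k + 1}" if freq > 1 else (ident or f"line{lineno}")
            )
            histories.append(EncounterHistory(label, dets))
    if not histories:
        raise FormatError("no histories found")
    widths = {h.n_occasions for h in histories}
    if len(widths) != 1:
        raise FormatError(f"ragged histories: occasion counts {sorted(widths)}")
    return histories


def read_capture_histories(source, dialect: str = "matrix-csv") -> list[EncounterHistory]:
    """Read encounter histories from matrix-CSV or MARK-style INP text.

    ``matrix-csv``: one row per individual, optional leading id column,
    0/1 fields (comma-separated or a single undelimited digit string).
    ``mark-inp``: optional ``/*id*/`` comment, digit string, optional integer
    frequency (expanded to repeated histories), ``;`` terminator.
    """
    text = _read_text(source)
    if dialect in ("matrix-csv", "csv", "matrix"):
        return _parse_matrix_csv(text)
    if dialect in ("mark-inp", "inp"):
        return _parse_mark_inp(text)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# summaries and sufficient statistics


def summarize(histories: Sequence[EncounterHistory]) -> dict[str, int]:
    """Counts of marked individuals, individuals resighted again, and encounters."""
    if not histories:
        raise ValueError("empty history list")
    return {
        "n_marked": len(histories),
        "n_resighted_again": sum(1 for h in histories if h.n_detections >= 2),
        "n_encounters": sum(h.n_detections for h in histories),
    }


def split_histories(histories: Sequence[EncounterHistory]) -> list[ReleaseSegment]:
    """Split each history at every detection (Pradel splitting).

    Every detection except one at the final occasion opens a release segment;
    the segment records the next detection occasion, or None if the individual
    was never seen again.
    """
    segments: list[ReleaseSegment] = []
    for h in histories:
        det_occs = [k + 1 for k, d in enumerate(h.detections) if d == 1]
        for a, b in zip(det_occs, det_occs[1:]):
            segments.append(ReleaseSegment(h.individual_id, a, b))
        last = det_occs[-1]
        if last < h.n_occasions:
            segments.append(ReleaseSegment(h.individual_id, last, None))
    return segments


def build_marray(histories: Sequence[EncounterHistory]) -> MArray:
    """Build the split-history m-array (releases include re-releases)."""
    if not histories:
        raise ValueError("empty history list")
    n_occ = histories[0].n_occasions
    if any(h.n_occasions != n_occ for h in histories):
        raise ValueError("histories have differing occasion counts")
    releases = np.zeros(n_occ, dtype=int)
    m = np.zeros((n_occ, n_occ), dtype=int)
    for seg in split_histories(histories):
        releases[seg.release_occasion - 1] += 1
        if seg.next_detection is not None:
            m[seg.release_occasion - 1, seg.next_detection - 1] += 1
    return MArray(n_occ, releases, m)


def histories_to_matrix(histories: Sequence[EncounterHistory]) -> np.ndarray:
    """Stack histories into an (n_individuals, n_occasions) 0/1 array."""
    return np.array([h.detections for h in histories], dtype=int)


def matrix_to_histories(matrix: np.ndarray, ids: Iterable[str] | None = None) -> list[EncounterHistory]:
    matrix = np.asarray(matrix, dtype=int)
    labels = list(ids) if ids is not None else [f"ind{i + 1}" for i in range(len(matrix))]
    return [
        EncounterHistory(lab, tuple(int(x) for x in row))
        for lab, row in zip(labels, matrix)
    ]


# ---------------------------------------------------------------------------
# m-array CSV I/O


def write_marray(marray: MArray, path) -> None:
    """Write m-array CSV: release occasion, R, next-recapture counts, never-again."""
    n = marray.n_occasions
    cols = {"release_occasion": np.arange(1, n + 1), "R": marray.releases}
    for j in range(2, n + 1):
        cols[f"m{j}"] = marray.next_recapture[:, j - 1]
    cols["never_again"] = marray.never_again
    pd.DataFrame(cols).to_csv(path, index=False)


def read_marray(path) -> MArray:
    """Read an m-array CSV written by :func:`write_marray` (or equivalent)."""
    df = pd.read_csv(path)
    n = len(df)
    releases = df["R"].to_numpy(dtype=int)
    m = np.zeros((n, n), dtype=int)
    for j in range(2, n + 1):
        col = f"m{j}"
        if col in df.columns:
            m[:, j - 1] = df[col].to_numpy(dtype=int)
    return MArray(n, releases, m)
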