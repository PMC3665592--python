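"""Positional weight matrix for the sigma-54 -24/-12 promoter element.

The sigma-54 (RpoN) holoenzyme recognizes a 16-bp element with strongly
conserved GG and GC dinucleotides at the -24 and -12 positions,
consensus ``TGGCACG-N4-TTGC(T/A)``.  This module holds the per-position
base-count model of that element and the 0-100 window score used
throughout the package: the sum of log base frequencies over the window,
rescaled linearly so that the column-wise worst string scores 0 and the
column-wise modal string scores 100.  The score is strictly monotone in
the window's likelihood under the matrix.

Matrices are stored as plain tab-delimited text (four labeled count rows
A/C/G/T over ``width`` columns, with ``n_sites`` and ``pseudocount``
metadata) so a user-supplied matrix — e.g. one estimated from a curated
collection of experimentally mapped sigma-54 promoters — can be dropped
in for the shipped consensus-derived default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    AmbiguousBaseError,
    InputError,
    PWMFormatError,
    UnscorableWindowError,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: floor for log(0): far below log of any attainable positive frequency,
#: keeps scores finite when a pseudocount of 0 leaves unobserved bases.
_LOG_FLOOR = math.log(np.finfo(float).tiny)

#: motif width of the -24/-12 element: TGGCACG (7) + N4 spacer + TTGC(T/A) (5).
DEFAULT_WIDTH = 16

#: 1-based matrix columns of the conserved dinucleotides.
DEFAULT_ELEMENTS: Mapping[str, tuple[int, ...]] = {"-24": (2, 3), "-12": (14, 15)}


def _encode_site(site: str) -> list[int]:
    try:
        return [_BASE_INDEX[b] for b in site.upper()]
    except KeyError as exc:
        raise AmbiguousBaseError(
            f"training site {site!r} contains a non-ACGT base"
        ) from exc


@dataclass(frozen=True)
class PWM:
    """Per-position base-count model of a fixed-width DNA motif.

    Parameters
    ----------
    counts
        Array of shape ``(width, 4)`` with non-negative per-position
        counts over A, C, G, T (in that order).
    pseudocount
        Added to every cell before frequencies are formed; keeps the log
        score defined when a base is unobserved among the training sites.
    n_sites
        Number of training sites the counts summarize (metadata).
    consensus_offsets
        Map from element label (e.g. ``"-24"``) to the 1-based matrix
        columns it occupies.
    """

    counts: np.ndarray
    pseudocount: float = 0.5
    n_sites: int | None = None
    consensus_offsets: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise InputError(f"counts must have shape (width, 4), got {counts.shape}")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise InputError("counts must be finite and non-negative")
        if np.any(counts.sum(axis=1) == 0):
            raise InputError("every position needs at least one positive count")
        if self.pseudocount < 0:
            raise InputError("pseudocount must be non-negative")
        object.__setattr__(self, "counts", counts)
        for label, cols in dict(self.consensus_offsets).items():
            for c in cols:
                if not 1 <= c <= counts.shape[0]:
                    raise InputError(f"element {label!r} column {c} outside matrix")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """``f_i(b) = (c_i(b) + pc) / (N_i + 4 pc)``; rows sum to 1."""
        totals = self.counts.sum(axis=1, keepdims=True)
        return (self.counts + self.pseudocount) / (totals + 4 * self.pseudocount)

    @property
    def log_frequencies(self) -> np.ndarray:
        f = self.frequencies
        out = np.full_like(f, _LOG_FLOOR)
        np.log(f, out=out, where=f > 0)
        return out

    @property
    def s_min(self) -> float:
        """Raw log score of the column-wise least-frequent string."""
        return float(self.log_frequencies.min(axis=1).sum())

    @property
    def s_max(self) -> float:
        """Raw log score of the column-wise modal string."""
        return float(self.log_frequencies.max(axis=1).sum())

    @property
    def modal_string(self) -> str:
        """Column-wise most frequent base (ties broken A < C < G < T)."""
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=1))

    @property
    def anti_modal_string(self) -> str:
        """Column-wise least frequent base (ties broken A < C < G < T)."""
        return "".join(BASES[i] for i in self.frequencies.argmin(axis=1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PWM):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.pseudocount == other.pseudocount
            and self.n_sites == other.n_sites
            and dict(self.consensus_offsets) == dict(other.consensus_offsets)
        )


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds and windows for scanning and promoter-gene linking.

    ``report_score`` is the scan floor (hits below it are discarded at
    scan time); ``link_score`` is the stricter cutoff applied when a hit
    is assigned to a gene; ``max_upstream`` is the largest allowed gap,
    in bp, between the motif's 3' end and the start codon.
    """

    report_score: float = 65.0
    link_score: float = 75.0
    max_upstream: int = 500
    ambiguity_policy: str = "skip_window"
    circular: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.report_score <= self.link_score <= 100:
            raise InputError(
                "need 0 <= report_score <= link_score <= 100, got "
                f"{self.report_score}/{self.link_score}"
            )
        if self.max_upstream < 1:
            raise InputError("max_upstream must be >= 1")
        if self.ambiguity_policy != "skip_window":
            raise InputError(f"unknown ambiguity_policy {self.ambiguity_policy!r}")


def build_pwm(
    aligned_sites: Sequence[str],
    pseudocount: float = 0.5,
    n_sites: int | None = None,
    consensus_offsets: Mapping[str, tuple[int, ...]] | None = None,
) -> PWM:
    """Tally aligned, equal-length ACGT sites into a PWM.

    The site order is irrelevant; duplicated site lists give the same
    frequencies as the originals.
    """
    sites = list(aligned_sites)
    if not sites:
        raise InputError("need at least one training site")
    width = len(sites[0])
    if width == 0:
        raise InputError("training sites must be non-empty")
    if any(len(s) != width for s in sites):
        raise AlignmentError("training sites must all have the same length")
    counts = np.zeros((width, 4), dtype=float)
    for site in sites:
        for pos, idx in enumerate(_encode_site(site)):
            counts[pos, idx] += 1
    return PWM(
        counts=counts,
        pseudocount=pseudocount,
        n_sites=len(sites) if n_sites is None else n_sites,
        consensus_offsets=dict(consensus_offsets or {}),
    )


def score_window(pwm: PWM, window: str) -> float:
    """Score one width-length window on the normalized 0-100 scale.

    ``score = 100 * (S_raw - s_min) / (s_max - s_min)`` with
    ``S_raw = sum_i log f_i(window_i)``.  A window containing an
    ambiguous base raises :class:`UnscorableWindowError`; callers scan
    past it.
    """
    if len(window) != pwm.width:
        raise InputError(
            f"window length {len(window)} != matrix width {pwm.width}"
        )
    try:
        idx = [_BASE_INDEX[b] for b in window.upper()]
    except KeyError as exc:
        raise UnscorableWindowError(
            f"window {window!r} contains an ambiguous base"
        ) from exc
    logf = pwm.log_frequencies
    # left-to-right accumulation, matching the scanner's per-offset sums
    # bit for bit so a window rescored here reproduces its scan score
    s_raw = 0.0
    for pos, base_idx in enumerate(idx):
        s_raw += float(logf[pos, base_idx])
    denom = pwm.s_max - pwm.s_min
    if denom == 0:  # fully uniform matrix: every window is modal
        return 100.0
    return float(np.clip(100.0 * (s_raw - pwm.s_min) / denom, 0.0, 100.0))


# ---------------------------------------------------------------------------
# tab-delimited matrix files


def write_pwm(pwm: PWM, path: str | Path) -> None:
    """Write a PWM as tab-delimited text (see :func:`read_pwm`)."""
    path = Path(path)
    lines = ["# sigma54scan PWM v1"]
    if pwm.n_sites is not None:
        lines.append(f"# n_sites: {pwm.n_sites}")
    lines.append(f"# pseudocount: {pwm.pseudocount:g}")
    if pwm.consensus_offsets:
        parts = [
            f"{label}={','.join(str(c) for c in cols)}"
            for label, cols in pwm.consensus_offsets.items()
        ]
        lines.append(f"# elements: {'; '.join(parts)}")
    lines.append("pos\t" + "\t".join(str(i + 1) for i in range(pwm.width)))
    for bi, base in enumerate(BASES):
        row = "\t".join(f"{v:g}" for v in pwm.counts[:, bi])
        lines.append(f"{base}\t{row}")
    path.write_text("\n".join(lines) + "\n")


def _parse_meta(comment_lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in comment_lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip().lower()] = value.strip()
    return meta


def _parse_elements(text: str) -> dict[str, tuple[int, ...]]:
    out: dict[str, tuple[int, ...]] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        label, _, cols = part.partition("=")
        out[label.strip()] = tuple(int(c) for c in cols.split(","))
    return out


def read_pwm(path: str | Path) -> PWM:
    """Read a tab-delimited PWM file.

    Format: ``#`` metadata lines (``n_sites``, ``pseudocount``,
    ``elements``), an optional ``pos`` header row, then exactly four
    rows labeled A, C, G, T each carrying ``width`` numeric counts.
    Columns are numbered 5'->3' in promoter orientation on the gene's
    coding strand.
    """
    path = Path(path)
    comments: list[str] = []
    rows: dict[str, list[float]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            comments.append(line)
            continue
        fields = line.split("\t")
        label = fields[0].strip().upper()
        if label == "POS":
            continue
        if label not in _BASE_INDEX:
            raise PWMFormatError(f"{path}:{lineno}: unexpected row label {fields[0]!r}")
        if label in rows:
            raise PWMFormatError(f"{path}:{lineno}: duplicate row for base {label}")
        try:
            values = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise PWMFormatError(f"{path}:{lineno}: non-numeric count") from exc
        if any(v < 0 for v in values):
            raise PWMFormatError(f"{path}:{lineno}: negative count")
        rows[label] = values
    if set(rows) != set(BASES):
        missing = sorted(set(BASES) - set(rows))
        raise PWMFormatError(f"{path}: need 4 base rows A,C,G,T; missing {missing}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1 or widths == {0}:
        raise PWMFormatError(f"{path}: base rows have unequal or zero column counts")
    meta = _parse_meta(comments)
    counts = np.column_stack([rows[b] for b in BASES])
    try:
        return PWM(
            counts=counts,
            pseudocount=float(meta.get("pseudocount", 0.5)),
            n_sites=int(meta["n_sites"]) if "n_sites" in meta else None,
            consensus_offsets=_parse_elements(meta.get("elements", "")),
        )
    except InputError as exc:
        raise PWMFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# shipped default matrix


def consensus_pwm(n_sites: int = 186, pseudocount: float = 0.5) -> PWM:
    """Consensus-derived default matrix for the -24/-12 element.

    Each consensus position of ``TGGCACG-N4-TTGC(T/A)`` puts all
    ``n_sites`` counts on the consensus base; the 4-bp spacer is
    uniform; the final degenerate position splits evenly between T and
    A.  The count scale mirrors the size of the curated promoter
    collections such matrices are usually estimated from.  Users with a
    site-derived matrix should load it with :func:`read_pwm` instead.
    """
    counts = np.zeros((DEFAULT_WIDTH, 4), dtype=float)
    consensus = "TGGCACG"
    for pos, base in enumerate(consensus):
        counts[pos, _BASE_INDEX[base]] = n_sites
    for pos in range(7, 11):  # N4 spacer
        counts[pos, :] = n_sites / 4.0
    for pos, base in enumerate("TTGC", start=11):
        counts[pos, _BASE_INDEX[base]] = n_sites
    counts[15, _BASE_INDEX["T"]] = n_sites / 2.0
    counts[15, _BASE_INDEX["A"]] = n_sites / 2.0
    return PWM(
        counts=counts,
        pseudocount=pseudocount,
        n_sites=n_sites,
        consensus_offsets=dict(DEFAULT_ELEMENTS),
    )


def load_default_pwm() -> PWM:
    """Load the consensus-derived matrix shipped with the package."""
    ref = resources.files("sigma54scan").joinpath("data/sigma54_consensus_pwm.tsv")
    with resources.as_file(ref) as path:
        return read_pwm(path)
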