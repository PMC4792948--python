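"""Read ingestion, junction-window extraction and per-position profiling.

Amplicon reads are handled by anchor matching rather than general alignment:
every amplicon class carries an invariant 5' and 3' flank around the
randomized window, and the window is recovered by locating those flanks with
a bounded-mismatch (substitution-only) scan and checking their spacing.
Reads failing the anchor match, the spacing check or carrying ambiguous
window bases are discarded with a reason code — this is the package's
operational definition of filtering out abnormal recombination events.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .errors import ConfigError, DataError
from .site_model import ALPHABET, BASE_INDEX, SiteModel

REJECT_REASONS = ("anchor_fail", "length_fail", "ambiguous_base")


# -- anchors ---------------------------------------------------------------


@dataclass(frozen=True)
class AnchorSet:
    """Invariant flanks bracketing the randomized-window span.

    ``left`` and ``right`` are the anchor sequences; the *span* is the
    stretch of ``span_length`` bases strictly between them, and
    ``window_offsets`` are the 0-based offsets of the P randomized positions
    within that span (the span may contain invariant bases when the window
    is not contiguous).
    """

    left: str
    right: str
    span_length: int
    window_offsets: tuple[int, ...]

    @classmethod
    def from_site(cls, site: SiteModel, anchor_len: int = 8) -> "AnchorSet":
        """Derive extraction anchors from the site geometry: ``anchor_len``
        invariant bases immediately 5' and 3' of the window span."""
        first, last = min(site.randomized_window), max(site.randomized_window)
        if first - anchor_len < 1 or last + anchor_len > len(site.top_strand):
            raise ConfigError(
                "site flanks too short for the requested anchor length"
            )
        top = site.top_strand
        return cls(
            left=top[first - 1 - anchor_len: first - 1],
            right=top[last: last + anchor_len],
            span_length=last - first + 1,
            window_offsets=tuple(p - first for p in site.randomized_window),
        )


def hamming(a: str, b: str) -> int:
    """Substitution distance between equal-length strings."""
    return sum(x != y for x, y in zip(a, b))


def _scan(seq: str, anchor: str, max_mm: int, start: int = 0) -> int:
    """Leftmost offset >= start where ``anchor`` matches within ``max_mm``
    substitutions; -1 if none."""
    la = len(anchor)
    for i in range(start, len(seq) - la + 1):
        if hamming(seq[i: i + la], anchor) <= max_mm:
            return i
    return -1


@dataclass(frozen=True)
class WindowResult:
    """Outcome of window extraction for one read."""

    window: str | None
    reason: str | None = None
    strand: str = "+"

    @property
    def ok(self) -> bool:
        return self.window is not None


def extract_window(
    read, anchors: AnchorSet, max_anchor_mismatch: int = 1
) -> WindowResult:
    """Recover the P-base randomized window from one read.

    The read is scanned for the left anchor on the given sequence and, if
    absent, on its reverse complement (the window is canonicalized to the
    top strand).  The right anchor must then match at exactly
    ``span_length`` bases downstream; a right anchor found at any other
    spacing signals a length-altering event (``length_fail``), an absent
    one an anchor failure (``anchor_fail``).  Windows containing non-ACGT
    characters are rejected as ``ambiguous_base``.
    """
    seq = _read_sequence(read)
    saw_wrong_spacing = False
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        i = _scan(s, anchors.left, max_anchor_mismatch)
        while i >= 0:
            span_start = i + len(anchors.left)
            j = span_start + anchors.span_length
            if j + len(anchors.right) <= len(s) and hamming(
                s[j: j + len(anchors.right)], anchors.right
            ) <= max_anchor_mismatch:
                span = s[span_start:j]
                window = "".join(span[o] for o in anchors.window_offsets)
                if any(c not in BASE_INDEX for c in window):
                    return WindowResult(None, "ambiguous_base", strand)
                return WindowResult(window, None, strand)
            # left anchor found but right not at the expected spacing: a
            # right anchor present elsewhere suggests a length-altering
            # event; keep scanning in case this left hit was spurious
            if _scan(s, anchors.right, max_anchor_mismatch, span_start) >= 0:
                saw_wrong_spacing = True
            i = _scan(s, anchors.left, max_anchor_mismatch, i + 1)
    reason = "length_fail" if saw_wrong_spacing else "anchor_fail"
    return WindowResult(None, reason, "+")


def _read_sequence(read) -> str:
    if isinstance(read, str):
        return read.upper()
    try:
        return str(read.seq).upper()
    except AttributeError as exc:
        raise DataError(f"malformed read record: {read!r}") from exc


# -- read classification ---------------------------------------------------


def classify_reads(
    reads: Iterable,
    class_anchors: Mapping[str, tuple[str, str]],
    max_mismatch: int = 1,
) -> dict[str, list]:
    """Partition reads into amplicon classes by their terminal anchors.

    ``class_anchors`` maps a class label (e.g. ``library``, ``left_site``,
    ``right_site``) to the (5' prefix, 3' suffix) pair that identifies its
    amplicon — the in-silico analogue of classifying reads by their PCR
    primer pair.  Both orientations of each read are tested; a read is
    assigned to a class only when exactly one class matches, otherwise it
    lands in ``unassigned``.  Raises :class:`ConfigError` when two classes
    share an identical anchor pair.
    """
    pairs = list(class_anchors.items())
    for (la, aa), (lb, ab) in itertools.combinations(pairs, 2):
        if aa == ab:
            raise ConfigError(
                f"anchor sets for classes {la!r} and {lb!r} are indistinguishable"
            )
    out: dict[str, list] = {label: [] for label in class_anchors}
    out["unassigned"] = []
    for read in reads:
        seq = _read_sequence(read)
        rc = reverse_complement(seq)
        hits = []
        for label, (up, down) in class_anchors.items():
            for s in (seq, rc):
                if len(s) >= len(up) + len(down) and (
                    hamming(s[: len(up)], up) <= max_mismatch
                    and hamming(s[-len(down):], down) <= max_mismatch
                ):
                    hits.append(label)
                    break
        if len(hits) == 1:
            out[hits[0]].append(read)
        else:
            out["unassigned"].append(read)
    return out


# -- profiling --------------------------------------------------------------


@dataclass
class PositionProfile:
    """Per-position base counts (P x 4, :data:`~xovermap.site_model.ALPHABET`
    order) with the frequencies derived from them.  ``wt`` optionally holds
    the wild-type base per position, enabling non-WT summaries."""

    counts: np.ndarray
    wt: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise DataError("counts must be a P x 4 matrix")

    @property
    def P(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> np.ndarray:
        """Total reads per position."""
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        n = self.n.astype(float)
        with np.errstate(invalid="ignore"):
            return np.where(n[:, None] > 0, self.counts / n[:, None], np.nan)

    def nonwt_counts(self, wt: str | None = None) -> np.ndarray:
        wt = wt or self.wt
        if wt is None or len(wt) != self.P:
            raise DataError("wild-type window required for non-WT summaries")
        wt_idx = np.array([BASE_INDEX[b] for b in wt])
        return self.n - self.counts[np.arange(self.P), wt_idx]

    def nonwt_rates(self, wt: str | None = None) -> np.ndarray:
        return self.nonwt_counts(wt) / self.n.astype(float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        freq = self.frequencies
        for j in range(self.P):
            for k, base in enumerate(ALPHABET):
                rows.append(
                    (j + 1, base, int(self.counts[j, k]), float(freq[j, k]),
                     (self.wt[j] if self.wt else ""))
                )
        return pd.DataFrame(
            rows, columns=["position", "base", "count", "frequency", "wt_base"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PositionProfile":
        P = int(df["position"].max())
        counts = np.zeros((P, 4), dtype=np.int64)
        wt = [""] * P
        for _, row in df.iterrows():
            counts[int(row["position"]) - 1, BASE_INDEX[row["base"]]] = row["count"]
            if row.get("wt_base"):
                wt[int(row["position"]) - 1] = row["wt_base"]
        return cls(counts=counts, wt="".join(wt) if all(wt) else None)


def profile_positions(
    windows: Sequence[str], wt: str | None = None
) -> PositionProfile:
    """Tally per-position base counts over equal-length window sequences."""
    windows = list(windows)
    if not windows:
        raise DataError("no usable reads: cannot profile an empty window set")
    P = len(windows[0])
    if any(len(w) != P for w in windows):
        raise DataError("windows have unequal lengths")
    arr = np.frombuffer("".join(windows).encode(), dtype=np.uint8).reshape(-1, P)
    counts = np.zeros((P, 4), dtype=np.int64)
    for k, base in enumerate(ALPHABET):
        counts[:, k] = (arr == ord(base)).sum(axis=0)
    if not np.array_equal(counts.sum(axis=1), np.full(P, len(windows))):
        raise DataError("windows contain non-ACGT characters")
    return PositionProfile(counts=counts, wt=wt)


# -- junction profile pairs -------------------------------------------------


@dataclass
class ClassCounts:
    """Retention bookkeeping for one amplicon class."""

    retained: int = 0
    discarded: dict = field(default_factory=lambda: {r: 0 for r in REJECT_REASONS})

    @property
    def total(self) -> int:
        return self.retained + sum(self.discarded.values())


@dataclass
class JunctionProfilePair:
    """The three per-position profiles of a crossover-mapping experiment:
    the library before recombination and the left and right cointegrate
    junction sites after, plus per-class retention counts."""

    library: PositionProfile
    left: PositionProfile
    right: PositionProfile
    counts: dict[str, ClassCounts] = field(default_factory=dict)


def extract_windows(
    reads: Iterable,
    anchors: AnchorSet,
    max_anchor_mismatch: int = 1,
) -> tuple[list[str], ClassCounts]:
    """Extract windows from many reads, tracking discard reasons."""
    windows: list[str] = []
    cc = ClassCounts()
    for read in reads:
        res = extract_window(read, anchors, max_anchor_mismatch)
        if res.ok:
            windows.append(res.window)
            cc.retained += 1
        else:
            cc.discarded[res.reason] += 1
    return windows, cc


def default_class_anchors(
    donor_context: tuple[str, str],
    recipient_context: tuple[str, str],
) -> dict[str, tuple[str, str]]:
    """Amplicon-class anchors for the standard three-amplicon design
    (library on the donor plasmid; left/right junctions of the cointegrate
    flanked by a donor- and a recipient-side primer respectively)."""
    return {
        "library": (donor_context[0], donor_context[1]),
        "left_site": (donor_context[0], recipient_context[1]),
        "right_site": (recipient_context[0], donor_context[1]),
    }


def profile_junctions(
    reads: Iterable,
    site: SiteModel,
    class_anchors: Mapping[str, tuple[str, str]],
    anchors: AnchorSet | None = None,
    max_anchor_mismatch: int = 1,
) -> JunctionProfilePair:
    """Classify a mixed read pool and profile each amplicon class.

    Convenience wrapper chaining :func:`classify_reads`,
    :func:`extract_windows` and :func:`profile_positions` for the three
    standard classes.
    """
    anchors = anchors or AnchorSet.from_site(site)
    wt = site.window_wt
    partitions = classify_reads(reads, class_anchors, max_anchor_mismatch)
    profiles = {}
    counts = {}
    for label in ("library", "left_site", "right_site"):
        windows, cc = extract_windows(
            partitions.get(label, ()), anchors, max_anchor_mismatch
        )
        counts[label] = cc
        if not windows:
            raise DataError(f"no usable reads for class {label!r}")
        profiles[label] = profile_positions(windows, wt=wt)
    counts["unassigned"] = ClassCounts(retained=0)
    counts["unassigned"].discarded = {"anchor_fail": len(partitions["unassigned"]),
                                      "length_fail": 0, "ambiguous_base": 0}
    return JunctionProfilePair(
        library=profiles["library"],
        left=profiles["left_site"],
        right=profiles["right_site"],
        counts=counts,
    )


# -- I/O --------------------------------------------------------------------


def read_fastx(path) -> list:
    """Read a FASTQ or FASTA file (by extension) into SeqRecords."""
    p = str(path)
    fmt = "fasta" if p.endswith((".fa", ".fasta", ".fna")) else "fastq"
    try:
        return list(SeqIO.parse(p, fmt))
    except ValueError as exc:
        raise DataError(f"cannot parse {p}: {exc}") from exc


def write_profile(profile: PositionProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_profile(path) -> PositionProfile:
    return PositionProfile.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))


def discard_log_frame(counts: Mapping[str, ClassCounts]) -> pd.DataFrame:
    rows = []
    for label, cc in counts.items():
        rows.append((label, "retained", cc.retained))
        for reason, k in cc.discarded.items():
            rows.append((label, reason, k))
    return pd.DataFrame(rows, columns=["class", "category", "reads"])
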