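"""Domain model for site-specific recombination sites and randomized libraries.

A recombination site (attI-like) is represented by its top strand written
5'->3', with the two integrase-binding boxes (R and L) annotated as 1-based
inclusive intervals and crossover points expressed as *boundaries*: an index
``k`` denotes the inter-base position between top-strand bases ``k`` and
``k+1``.  Boundaries rather than positions are used because strand exchange
happens between bases, and the inference target downstream is precisely such
an inter-base location.

The randomized-library design follows the single-position scheme: the pool is
the uniform mixture of P sub-libraries, each carrying one fully random base at
one designated window position.  The per-position marginal base distribution
of such a pool is available in closed form (see
:func:`expected_position_distribution`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError, CoordinateError

#: Canonical base ordering used by every frequency matrix in the package.
ALPHABET = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True, order=True)
class Interval:
    """1-based inclusive interval on the top strand."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(f"invalid interval ({self.start}, {self.end})")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class SiteModel:
    """A double-stranded recombination site in top-strand coordinates.

    Parameters
    ----------
    name : identifier.
    top_strand : DNA string (A/C/G/T), 5'->3'.
    r_box, l_box : integrase-binding box intervals (1-based inclusive).
    bs_crossover : boundary index of the bottom-strand exchange point
        (the bottom strand reads 5'-AA^C-3' there), mapped to top-strand
        coordinates: exchange between top bases ``k`` and ``k+1``.
    ts_crossover : boundary index of the top-strand exchange point, or
        ``None`` while unknown (it is the quantity the package infers).
    randomized_window : ordered tuple of the P top-strand positions eligible
        for randomization in library designs built on this site.
    """

    name: str
    top_strand: str
    r_box: Interval
    l_box: Interval
    bs_crossover: int
    randomized_window: tuple[int, ...]
    ts_crossover: int | None = None

    # -- geometry helpers -------------------------------------------------

    def __len__(self) -> int:
        return len(self.top_strand)

    @property
    def P(self) -> int:
        """Number of randomizable window positions."""
        return len(self.randomized_window)

    @property
    def window_wt(self) -> str:
        """Wild-type bases at the window positions, in window order."""
        return "".join(self.top_strand[p - 1] for p in self.randomized_window)

    def window_bases(self, molecule: str) -> str:
        """Window bases of a concrete molecule sharing this geometry."""
        if len(molecule) != len(self.top_strand):
            raise CoordinateError(
                f"molecule length {len(molecule)} != site length {len(self.top_strand)}"
            )
        return "".join(molecule[p - 1] for p in self.randomized_window)

    def with_window_base(self, ordinal: int, base: str) -> str:
        """Top strand with window position ``ordinal`` (1-based) set to ``base``."""
        if not 1 <= ordinal <= self.P:
            raise CoordinateError(f"window ordinal {ordinal} outside 1..{self.P}")
        pos = self.randomized_window[ordinal - 1]
        s = self.top_strand
        return s[: pos - 1] + base + s[pos:]

    def boundary_coordinate(self, b: int) -> int:
        """Map a window-ordinal boundary ``b`` (0..P) to a top-strand boundary.

        ``b`` means "between window ordinals b and b+1"; the returned index
        ``k`` means "between top-strand bases k and k+1".  For ``b = 0`` the
        cut falls immediately 5' of the first window position; otherwise it
        falls immediately 3' of window ordinal ``b``.  When consecutive window
        ordinals are not adjacent on the top strand the cut is placed directly
        after ordinal ``b``, so all intervening invariant bases travel with
        the 3' moiety.
        """
        if not 0 <= b <= self.P:
            raise CoordinateError(f"boundary {b} outside 0..{self.P}")
        if b == 0:
            return self.randomized_window[0] - 1
        return self.randomized_window[b - 1]

    # -- spacer geometry used by the validation rule ----------------------

    def _allowed_window_positions(self) -> set[int]:
        """L box, the two spacer positions adjacent to it, and the top-strand
        base paired with the bottom-strand crossover C of the R box."""
        allowed = set(self.l_box.positions())
        # spacer side: the L box faces the R box across the spacer
        if self.l_box.end < self.r_box.start:
            allowed.update({self.l_box.end + 1, self.l_box.end + 2})
        else:
            allowed.update({self.l_box.start - 2, self.l_box.start - 1})
        allowed.add(self.bs_crossover)
        return allowed


def validate_site(site: SiteModel) -> list[str]:
    """Check SiteModel invariants; returns a list of violation messages.

    An empty list means the site is well formed.  Violations are returned
    rather than raised so a config loader can report all of them at once.
    """
    violations: list[str] = []
    n = len(site.top_strand)
    bad = sorted({c for c in site.top_strand if c not in BASE_INDEX})
    if bad:
        violations.append(
            f"top_strand contains non-ACGT characters: {''.join(bad)}"
        )
    for label, box in (("r_box", site.r_box), ("l_box", site.l_box)):
        if box.end > n:
            violations.append(f"{label} {box.start}-{box.end} exceeds site length {n}")
    if site.r_box.overlaps(site.l_box):
        violations.append("r_box and l_box overlap")
    if not 1 <= site.bs_crossover < n:
        violations.append(f"bs_crossover boundary {site.bs_crossover} outside 1..{n - 1}")
    if site.ts_crossover is not None and not 0 <= site.ts_crossover <= n:
        violations.append(f"ts_crossover boundary {site.ts_crossover} outside 0..{n}")
    if len(set(site.randomized_window)) != len(site.randomized_window):
        violations.append("randomized_window has duplicate positions")
    if list(site.randomized_window) != sorted(site.randomized_window):
        violations.append("randomized_window positions are not in 5'->3' order")
    allowed = site._allowed_window_positions()
    for p in site.randomized_window:
        if not 1 <= p <= n:
            violations.append(f"window position {p} outside site (1..{n})")
        elif p not in allowed:
            violations.append(
                f"window position {p} outside the L box, its two adjacent "
                "spacer positions, and the R-box crossover base"
            )
    return violations


@dataclass(frozen=True)
class LibrarySpec:
    """Randomization design: P single-position sub-libraries, mixed uniformly.

    Each molecule of the pool carries exactly one fully random base (so 1/4 of
    "randomized" molecules are in fact wild type at their designated
    position).  ``mixing`` gives the weight of each sub-library in the pool;
    the default is the uniform 1/P of the published design.
    """

    site: SiteModel
    positions: tuple[int, ...] = ()
    alphabet: tuple[str, ...] = ALPHABET
    mixing: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.positions:
            object.__setattr__(self, "positions", tuple(self.site.randomized_window))
        if not self.mixing:
            p = 1.0 / len(self.positions)
            object.__setattr__(self, "mixing", (p,) * len(self.positions))
        if len(self.mixing) != len(self.positions):
            raise ConfigError("mixing weights do not match positions")
        if abs(sum(self.mixing) - 1.0) > 1e-9:
            raise ConfigError("mixing weights must sum to 1")
        if len(self.alphabet) != 4:
            raise ConfigError("alphabet must have 4 bases")

    @property
    def P(self) -> int:
        return len(self.positions)


def expected_position_distribution(spec: LibrarySpec, position: int) -> np.ndarray:
    """Closed-form marginal base distribution at a top-strand position.

    For a randomized position carrying mixing weight ``w`` (uniform design:
    ``w = 1/P``), a molecule drawn from the pool is randomized there with
    probability ``w`` and then uniform over the 4 bases, so

        P(WT base)      = 1 - w * 3/4
        P(each non-WT)  = w * 1/4

    (P = 10 gives 92.5% WT and 2.5% per non-WT base).  Non-randomized
    positions are wild type with probability 1.

    Returns a length-4 probability vector in :data:`ALPHABET` order.
    """
    site = spec.site
    if not 1 <= position <= len(site.top_strand):
        raise CoordinateError(
            f"position {position} outside site (1..{len(site.top_strand)})"
        )
    wt = site.top_strand[position - 1]
    dist = np.zeros(4)
    if position in spec.positions:
        w = spec.mixing[spec.positions.index(position)]
        dist[:] = w * 0.25
        dist[BASE_INDEX[wt]] = 1.0 - w * 0.75
    else:
        dist[BASE_INDEX[wt]] = 1.0
    return dist


def expected_window_nonwt(spec: LibrarySpec) -> float:
    """Aggregate non-WT probability at a (uniformly mixed) randomized
    position: (3/4)/P.  0.075 for the P=10 design."""
    return 0.75 / spec.P


# -- strand-specific restriction markers (mismatched covalent circles) -----


class NarIState(enum.Enum):
    PLUS = "NarI+"
    MINUS = "NarI-"


class SacIIState(enum.Enum):
    PLUS = "SacII+"
    MINUS = "SacII-"


@dataclass(frozen=True)
class StrandMarkerPair:
    """Restriction-marker genotype of one clone derived from a mismatched
    covalent circle whose two strands were tagged with a NarI and a SacII
    site mutation respectively."""

    nari: NarIState
    sacii: SacIIState

    @property
    def label(self) -> str:
        return f"{self.nari.value}/{self.sacii.value}"


#: Clone genotype after transfer + replication of the bottom strand.
BS_TRANSFER_PROFILE = StrandMarkerPair(NarIState.MINUS, SacIIState.PLUS)
#: Clone genotype after transfer + replication of the top strand.
TS_TRANSFER_PROFILE = StrandMarkerPair(NarIState.PLUS, SacIIState.MINUS)

#: All four single-genotype restriction classes, in reporting order.
MARKER_CLASSES = (
    StrandMarkerPair(NarIState.PLUS, SacIIState.MINUS),
    StrandMarkerPair(NarIState.MINUS, SacIIState.PLUS),
    StrandMarkerPair(NarIState.PLUS, SacIIState.PLUS),
    StrandMarkerPair(NarIState.MINUS, SacIIState.MINUS),
)


# -- bundled default site ---------------------------------------------------

#: Window-ordinal boundary of the top-strand crossover of the bundled site:
#: between the two adenines of the 5'-AAC-3' triplet at the L-box border
#: (window ordinals 6 and 7).
DEFAULT_TS_BOUNDARY = 6


def default_site(name: str = "attI1_like") -> SiteModel:
    """The bundled attI1-like site.

    Top strand (39 bp, synthetic flanks):

    ``TGGCCAAA | CCCTAAA | CG | TAAGC | GTTACCAGT | ATGTGGTG``
    (flank | L box 9-15 | adjacent spacer 16-17 | spacer | R box 23-31 | flank)

    The L box carries the canonical 5'-CCCTAAA-3' sequence and, with the
    first adjacent spacer base C, forms the border 5'-AAC-3' triplet whose
    two adenines (positions 14/15, window ordinals 6/7) flank the top-strand
    crossover.  The R box starts 5'-GTT-3' so its bottom strand reads
    5'-AA^C-3'; the bottom-strand crossover boundary is 23 and the top-strand
    G at position 23 pairs with the crossover C (the tenth randomized
    position).  The 8-bp flanks outside the boxes are documented synthetic
    placeholders, chosen to give unique extraction anchors on both strands,
    and are freely configurable.
    """
    top = "TGGCCAAA" + "CCCTAAA" + "CG" + "TAAGC" + "GTTACCAGT" + "ATGTGGTG"
    return SiteModel(
        name=name,
        top_strand=top,
        l_box=Interval(9, 15),
        r_box=Interval(23, 31),
        bs_crossover=23,
        ts_crossover=14,
        randomized_window=tuple(range(9, 18)) + (23,),
    )


def default_library_spec() -> LibrarySpec:
    """The 10-position single-random-base library on the bundled site."""
    return LibrarySpec(site=default_site())


# -- plain-text config ------------------------------------------------------


def site_from_dict(d: dict) -> SiteModel:
    """Build and validate a SiteModel from a parsed config mapping."""
    try:
        site = SiteModel(
            name=str(d["name"]),
            top_strand=str(d["top_strand"]).upper(),
            r_box=Interval(*d["r_box"]),
            l_box=Interval(*d["l_box"]),
            bs_crossover=int(d["bs_crossover"]),
            randomized_window=tuple(int(p) for p in d["randomized_window"]),
            ts_crossover=(None if d.get("ts_crossover") is None
                          else int(d["ts_crossover"])),
        )
    except KeyError as exc:
        raise ConfigError(f"site config missing key: {exc.args[0]}") from exc
    except (TypeError, ValueError, CoordinateError) as exc:
        raise ConfigError(f"malformed site config: {exc}") from exc
    violations = validate_site(site)
    if violations:
        raise ConfigError(violations)
    return site


def site_to_dict(site: SiteModel) -> dict:
    return {
        "name": site.name,
        "top_strand": site.top_strand,
        "r_box": [site.r_box.start, site.r_box.end],
        "l_box": [site.l_box.start, site.l_box.end],
        "bs_crossover": site.bs_crossover,
        "ts_crossover": site.ts_crossover,
        "randomized_window": list(site.randomized_window),
    }


def load_site_config(path) -> SiteModel:
    """Load a site definition from a YAML key/value config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("site config must be a mapping")
    return site_from_dict(doc.get("site", doc))
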