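"""Forward simulation of library construction, integrase recombination and
amplicon sequencing.

This module is the fixture generator for the whole package: it draws
randomized-site libraries, performs reciprocal strand exchange at a chosen
boundary under one of three Holliday-junction resolution pathways, traces the
strand-specific restriction markers of mismatched covalent circles, and emits
substitution-error sequencing reads as FASTQ.  All stochastic functions take
an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, DataError
from .site_model import (
    ALPHABET,
    BS_TRANSFER_PROFILE,
    TS_TRANSFER_PROFILE,
    LibrarySpec,
    SiteModel,
    StrandMarkerPair,
)


class Pathway(enum.Enum):
    """How the Holliday junction formed by the first strand exchange is
    resolved.  ``SECOND_EXCHANGE`` is the classical Y-recombinase pathway
    (a second cleavage/transfer); the two replicative pathways resolve the
    junction by replication after a single bottom- or top-strand exchange."""

    SECOND_EXCHANGE = "second_exchange"
    REPLICATIVE_BS = "replicative_bs"
    REPLICATIVE_TS = "replicative_ts"


class Orientation(enum.Enum):
    INTERMOLECULAR = "intermolecular"
    DIRECT = "direct"
    INVERTED = "inverted"


class Outcome(enum.Enum):
    COINTEGRATE = "cointegrate"
    EXCISION = "excision"
    INVERSION = "inversion"
    ABORTIVE_LINEAR = "abortive_linear"


#: Reaction outcome as a pure function of (pathway, orientation).
#: Intermolecular reactions fuse the replicons into a cointegrate whatever
#: the pathway.  Between direct repeats both pathways excise the intervening
#: segment.  Between inverted repeats only the second strand exchange is
#: productive (it inverts the segment); replicative resolution linearizes
#: the replicon and is abortive.
OUTCOME_TABLE: dict[tuple[Pathway, Orientation], Outcome] = {}
for _p in Pathway:
    OUTCOME_TABLE[(_p, Orientation.INTERMOLECULAR)] = Outcome.COINTEGRATE
    OUTCOME_TABLE[(_p, Orientation.DIRECT)] = Outcome.EXCISION
OUTCOME_TABLE[(Pathway.SECOND_EXCHANGE, Orientation.INVERTED)] = Outcome.INVERSION
OUTCOME_TABLE[(Pathway.REPLICATIVE_BS, Orientation.INVERTED)] = Outcome.ABORTIVE_LINEAR
OUTCOME_TABLE[(Pathway.REPLICATIVE_TS, Orientation.INVERTED)] = Outcome.ABORTIVE_LINEAR


@dataclass(frozen=True)
class RecombinationEvent:
    """One simulated recombination reaction between two concrete sites."""

    donor: str
    recipient: str
    boundary: int
    pathway: Pathway
    orientation: Orientation
    left_site: str
    right_site: str
    outcome: Outcome


# -- library construction ---------------------------------------------------


def exhaustive_library(spec: LibrarySpec) -> list[str]:
    """The nominal library: one molecule per (position, base) combination.

    For the P=10, 4-letter design this is the n=40 pool of the published
    protocol; note the base may equal the wild type, so only 3P of the 4P
    molecules are sequence-distinct from WT (plus P copies of WT itself).
    """
    site = spec.site
    out = []
    for ordinal in range(1, spec.P + 1):
        for base in spec.alphabet:
            out.append(site.with_window_base(ordinal, base))
    return out


def draw_library(spec: LibrarySpec, n_molecules: int, seed: int) -> list[str]:
    """Draw concrete library molecules: each carries exactly one randomized
    position (uniform over the P sub-libraries) holding a uniform base."""
    if n_molecules <= 0:
        raise DataError(f"n_molecules must be positive, got {n_molecules}")
    rng = np.random.default_rng(seed)
    ordinals = rng.choice(spec.P, size=n_molecules, p=np.asarray(spec.mixing)) + 1
    bases = rng.integers(0, 4, size=n_molecules)
    site = spec.site
    return [
        site.with_window_base(int(o), spec.alphabet[int(b)])
        for o, b in zip(ordinals, bases)
    ]


# -- strand exchange --------------------------------------------------------


def recombine(
    donor_molecule: str,
    recipient: SiteModel,
    boundary: int,
    pathway: Pathway,
    orientation: Orientation,
    seed: int | None = None,
) -> RecombinationEvent:
    """Recombine a concrete donor molecule with a recipient site.

    Under the second strand exchange the two products are reciprocal hybrids
    split at window-ordinal boundary ``boundary``: the left junction carries
    donor window ordinals 1..b and recipient ordinals b+1..P, the right
    junction the complementary partition.  Under either replicative pathway
    only the first (bottom-strand) exchange takes place before replication,
    so the split falls at the bottom-strand crossover of the R box and the
    randomized window is not split: one junction carries the donor window
    intact, the other the recipient window intact.

    ``seed`` is accepted for interface symmetry; the event is fully
    determined by its arguments.
    """
    del seed
    site = recipient
    if len(donor_molecule) != len(site.top_strand):
        raise CoordinateError("donor molecule does not match recipient geometry")
    if not 0 <= boundary <= site.P:
        raise CoordinateError(f"boundary {boundary} outside 0..{site.P}")
    pathway = Pathway(pathway)
    orientation = Orientation(orientation)
    rec = site.top_strand
    if pathway is Pathway.SECOND_EXCHANGE:
        cut = site.boundary_coordinate(boundary)
    else:
        cut = site.bs_crossover
    left = donor_molecule[:cut] + rec[cut:]
    right = rec[:cut] + donor_molecule[cut:]
    return RecombinationEvent(
        donor=donor_molecule,
        recipient=rec,
        boundary=boundary,
        pathway=pathway,
        orientation=orientation,
        left_site=left,
        right_site=right,
        outcome=OUTCOME_TABLE[(pathway, orientation)],
    )


# -- mismatched-circle marker tracing --------------------------------------


@dataclass(frozen=True)
class MarkerPopulation:
    """Plasmid population recovered from one clone after replication of a
    recombined mismatched circle.  A homogeneous population digests cleanly;
    a mixed one gives partial restriction profiles with both enzymes."""

    classes: tuple[StrandMarkerPair, ...]

    @property
    def mixed(self) -> bool:
        return len(self.classes) > 1


def trace_circle_markers(pathway: Pathway) -> MarkerPopulation:
    """Predict the restriction-marker population for each resolution pathway.

    Transfer + replication of the bottom strand fixes the bottom strand's
    tags (SacII+/NarI-); the top strand gives SacII-/NarI+.  A double
    exchange transfers both mismatched strands, so replication segregates
    both genotypes into a mixed population.
    """
    pathway = Pathway(pathway)
    if pathway is Pathway.REPLICATIVE_BS:
        return MarkerPopulation((BS_TRANSFER_PROFILE,))
    if pathway is Pathway.REPLICATIVE_TS:
        return MarkerPopulation((TS_TRANSFER_PROFILE,))
    return MarkerPopulation((BS_TRANSFER_PROFILE, TS_TRANSFER_PROFILE))


def simulate_circle_assay(
    n_clones: int,
    strand_bias: float = 0.5,
    doubles_rate: float = 0.0,
    seed: int | None = None,
) -> list[StrandMarkerPair]:
    """Simulate single-strand transfer events from a mismatched-circle prep.

    Each clone derives from the transfer of one strand: the bottom strand
    with probability ``strand_bias`` (default 0.5: equal strand reactivity,
    the behaviour observed for symmetric double-stranded reactions), the top
    strand otherwise.  ``doubles_rate`` models the small fraction of circles
    mis-assembled from two copies of the same strand, which yield
    NarI+/SacII+ or NarI-/SacII- clones; the default models a clean prep.
    """
    if n_clones <= 0:
        raise DataError("n_clones must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n_clones)
    doubles = rng.random(n_clones) < doubles_rate
    double_kind = rng.random(n_clones) < 0.5
    from .site_model import MARKER_CLASSES

    out: list[StrandMarkerPair] = []
    for i in range(n_clones):
        if doubles[i]:
            out.append(MARKER_CLASSES[2] if double_kind[i] else MARKER_CLASSES[3])
        elif u[i] < strand_bias:
            out.append(BS_TRANSFER_PROFILE)
        else:
            out.append(TS_TRANSFER_PROFILE)
    return out


# -- amplicon contexts ------------------------------------------------------

#: Invariant plasmid context flanking the donor (library-carrying) site and
#: the recipient site in the simulated amplicons.  They stand in for the
#: distinct PCR primer pairs that identify each amplicon class.
DONOR_CONTEXT = ("GGGTCTGA", "CTGATGTA")
RECIPIENT_CONTEXT = ("ATAGACCC", "CAAAAGGG")


def library_amplicon(molecule: str) -> str:
    return DONOR_CONTEXT[0] + molecule + DONOR_CONTEXT[1]


def left_junction_amplicon(left_site: str) -> str:
    return DONOR_CONTEXT[0] + left_site + RECIPIENT_CONTEXT[1]


def right_junction_amplicon(right_site: str) -> str:
    return RECIPIENT_CONTEXT[0] + right_site + DONOR_CONTEXT[1]


# -- cointegrate pools ------------------------------------------------------


@dataclass
class CointegratePool:
    """Products of many intermolecular second-strand-exchange reactions."""

    events: list[RecombinationEvent]
    left_amplicons: list[str]
    right_amplicons: list[str]


def simulate_cointegrate_pool(
    spec: LibrarySpec,
    boundary: int,
    n_events: int,
    seed: int,
    partner: SiteModel | None = None,
    acceptance: Sequence[float] | None = None,
) -> CointegratePool:
    """Library x partner intermolecular reactions at a fixed crossover.

    Donors are drawn from the library; each recombines with the (wild-type)
    partner site through the second strand exchange at window boundary
    ``boundary``, yielding the two hybrid junction sites of a cointegrate.

    ``acceptance`` optionally models per-position sequence stringency: entry
    ``j`` (0-based window ordinal) is the probability that a donor carrying a
    non-WT base at ordinal ``j+1`` is accepted by the integrase; rejected
    donors are resampled (wild-type donors are always accepted).
    """
    if n_events <= 0:
        raise DataError("n_events must be positive")
    site = spec.site
    partner = partner or site
    if acceptance is not None and len(acceptance) != spec.P:
        raise CoordinateError("acceptance must have one entry per window position")
    rng = np.random.default_rng(seed)
    wt_window = site.window_wt
    events: list[RecombinationEvent] = []
    # draw in batches; rejection-sample when stringency is modelled
    while len(events) < n_events:
        batch = draw_library(spec, n_events - len(events),
                             int(rng.integers(0, 2**31 - 1)))
        for mol in batch:
            if acceptance is not None:
                window = site.window_bases(mol)
                diff = [j for j, (a, b) in enumerate(zip(window, wt_window)) if a != b]
                if diff and rng.random() >= acceptance[diff[0]]:
                    continue
            events.append(
                recombine(mol, partner, boundary,
                          Pathway.SECOND_EXCHANGE, Orientation.INTERMOLECULAR)
            )
    return CointegratePool(
        events=events,
        left_amplicons=[left_junction_amplicon(e.left_site) for e in events],
        right_amplicons=[right_junction_amplicon(e.right_site) for e in events],
    )


# -- sequencing-read simulation ---------------------------------------------

ABNORMAL_MODES = ("truncate", "anchor_mutate", "insert", "ambiguous")


@dataclass
class ReadSet:
    """Simulated reads plus their ground truth (template index, corruption
    mode, strand), keyed by read id."""

    records: list[SeqRecord]
    truth: pd.DataFrame

    def sequences(self) -> list[str]:
        return [str(r.seq) for r in self.records]


def _substitute(seq: str, pos: int, rng: np.random.Generator) -> str:
    alternatives = [b for b in ALPHABET if b != seq[pos]]
    return seq[:pos] + alternatives[int(rng.integers(0, 3))] + seq[pos + 1:]


def simulate_reads(
    templates: Sequence[str],
    depth: int,
    error_rate: float = 0.001,
    abnormal_fraction: float = 0.0,
    seed: int | None = None,
    template_mode: str = "uniform",
    both_strands: bool = False,
    anchors=None,
    read_id_prefix: str = "read",
    phred: int = 38,
) -> ReadSet:
    """Simulate single-end amplicon reads from a pool of template sequences.

    Each read is a full template copy with i.i.d. per-base substitution
    errors at ``error_rate`` (uniform over the three alternative bases).
    With probability ``abnormal_fraction`` a read is corrupted to mimic an
    abnormal recombination event or sequencing artifact — truncated, anchor-
    mutated, length-shifted by a 2-base insertion, or carrying an ambiguous
    base; these modes are the simulator's own taxonomy of non-canonical
    products and exist to exercise downstream filters.  Passing the
    extraction ``anchors`` (an :class:`~xovermap.seq_pipeline.AnchorSet`)
    aims each corruption at the anchored window so that every abnormal read
    is guaranteed to fail the filter; without it corruption coordinates are
    generic.  ``template_mode`` is ``"uniform"`` (templates sampled
    uniformly at random) or ``"cycle"`` (round-robin, giving exact coverage
    when depth is a multiple of the pool size).  With ``both_strands`` half
    the reads are reverse-complemented.
    """
    if depth <= 0:
        raise DataError("depth must be positive")
    if not 0 <= error_rate < 1:
        raise DataError("error_rate must be in [0, 1)")
    if not 0 <= abnormal_fraction < 1:
        raise DataError("abnormal_fraction must be in [0, 1)")
    if not templates:
        raise DataError("no templates supplied")
    rng = np.random.default_rng(seed)
    if template_mode == "cycle":
        template_idx = np.arange(depth) % len(templates)
    elif template_mode == "uniform":
        template_idx = rng.integers(0, len(templates), size=depth)
    else:
        raise ValueError(f"unknown template_mode {template_mode!r}")
    abnormal = rng.random(depth) < abnormal_fraction
    flip = rng.random(depth) < 0.5 if both_strands else np.zeros(depth, bool)

    records: list[SeqRecord] = []
    rows = []
    width = max(6, len(str(depth)))
    for i in range(depth):
        seq = templates[int(template_idx[i])]
        mode = ""
        if abnormal[i]:
            mode = ABNORMAL_MODES[int(rng.integers(0, len(ABNORMAL_MODES)))]
            seq = _corrupt(seq, mode, rng, anchors)
        n_err = rng.binomial(len(seq), error_rate)
        for pos in rng.choice(len(seq), size=n_err, replace=False):
            if seq[int(pos)] in BASE_INDEX_LOCAL:
                seq = _substitute(seq, int(pos), rng)
        if flip[i]:
            seq = reverse_complement(seq)
        rid = f"{read_id_prefix}_{i:0{width}d}"
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [phred] * len(seq)
        records.append(rec)
        rows.append((rid, int(template_idx[i]), mode, "-" if flip[i] else "+"))
    truth = pd.DataFrame(rows, columns=["read_id", "template_index",
                                        "abnormal_mode", "strand"])
    return ReadSet(records=records, truth=truth)


BASE_INDEX_LOCAL = frozenset(ALPHABET)


def _corrupt(seq: str, mode: str, rng: np.random.Generator, anchors=None) -> str:
    """Apply one abnormal-read corruption.

    With anchor geometry: truncation ends the read mid-span (3' anchor
    lost), insertion lands inside the span (spacing broken), anchor
    mutation puts three substitutions in the 5' anchor (mismatch budget
    exceeded), and ambiguity puts an N at a randomized window position.
    Without geometry, coordinates fall in the central portion of the read.
    """
    n = len(seq)
    la = seq.find(anchors.left) if anchors is not None else -1
    if la >= 0:
        span_start = la + len(anchors.left)
        if mode == "truncate":
            keep = int(rng.integers(span_start + 1, span_start + anchors.span_length))
            return seq[:keep]
        if mode == "insert":
            pos = int(rng.integers(span_start + 1, span_start + anchors.span_length))
            ins = "".join(ALPHABET[int(b)] for b in rng.integers(0, 4, 2))
            return seq[:pos] + ins + seq[pos:]
        if mode == "anchor_mutate":
            k = min(3, len(anchors.left))
            for off in rng.choice(len(anchors.left), size=k, replace=False):
                seq = _substitute(seq, la + int(off), rng)
            return seq
        if mode == "ambiguous":
            off = anchors.window_offsets[int(rng.integers(0, len(anchors.window_offsets)))]
            pos = span_start + off
            return seq[:pos] + "N" + seq[pos + 1:]
    # generic fallback coordinates
    if mode == "truncate":
        keep = int(rng.integers(n // 4, max(n // 4 + 1, n // 2)))
        return seq[:keep]
    if mode == "insert":
        pos = int(rng.integers(n // 3, 2 * n // 3))
        ins = "".join(ALPHABET[int(b)] for b in rng.integers(0, 4, 2))
        return seq[:pos] + ins + seq[pos:]
    if mode == "anchor_mutate":
        for pos in rng.choice(max(3, n // 4), size=3, replace=False):
            seq = _substitute(seq, int(pos), rng)
        return seq
    if mode == "ambiguous":
        pos = int(rng.integers(n // 3, 2 * n // 3))
        return seq[:pos] + "N" + seq[pos + 1:]
    raise ValueError(f"unknown corruption mode {mode!r}")


# -- count-level junction simulation ---------------------------------------


def simulate_junction_counts(
    boundary: int,
    depth: int,
    error_rate: float,
    seed: int,
    spec: LibrarySpec | None = None,
    expected_nonwt: float | None = None,
):
    """Directly simulate per-position base counts of the three profiles.

    Equivalent in distribution (position-marginally) to running the full
    read pipeline on an error-only simulation, but at count level: at each
    window position the non-WT read count is Binomial(depth, p) with
    p = q(1-e) + (1-q)e on the side of the junction that retains the donor
    moiety (q the library non-WT rate, e the substitution error rate) and
    p = e on the other side; non-WT counts are split uniformly over the
    three alternative bases.  Used by the power/recovery analyses, where
    per-position counts are sufficient statistics.

    Returns a :class:`~xovermap.seq_pipeline.JunctionProfilePair`.
    """
    from .seq_pipeline import JunctionProfilePair, PositionProfile
    from .site_model import default_library_spec, expected_window_nonwt

    spec = spec or default_library_spec()
    P = spec.P
    if not 0 <= boundary <= P:
        raise CoordinateError(f"boundary {boundary} outside 0..{P}")
    q = expected_window_nonwt(spec) if expected_nonwt is None else expected_nonwt
    e = error_rate
    p_hot = q * (1 - e) + (1 - q) * e
    p_cold = e
    rng = np.random.default_rng(seed)
    wt = spec.site.window_wt

    def profile(p_vec: np.ndarray) -> PositionProfile:
        counts = np.zeros((P, 4), dtype=np.int64)
        nonwt = rng.binomial(depth, p_vec)
        for j in range(P):
            split = rng.multinomial(nonwt[j], [1 / 3] * 3)
            alt = [i for i in range(4) if ALPHABET[i] != wt[j]]
            counts[j, alt] = split
            counts[j, ALPHABET.index(wt[j])] = depth - nonwt[j]
        return PositionProfile(counts=counts, wt=wt)

    ordinals = np.arange(1, P + 1)
    left = profile(np.where(ordinals <= boundary, p_hot, p_cold))
    right = profile(np.where(ordinals > boundary, p_hot, p_cold))
    library = profile(np.full(P, p_hot))
    return JunctionProfilePair(library=library, left=left, right=right)


# -- writers ----------------------------------------------------------------


def _as_handle(path):
    return path if hasattr(path, "write") else str(path)


def write_fastq(reads: ReadSet | Sequence[SeqRecord], path) -> int:
    records = reads.records if isinstance(reads, ReadSet) else list(reads)
    return SeqIO.write(records, _as_handle(path), "fastq")


def write_fasta(sequences: Mapping[str, str] | Sequence[SeqRecord], path) -> int:
    if isinstance(sequences, Mapping):
        records = [SeqRecord(Seq(s), id=name, description="")
                   for name, s in sequences.items()]
    else:
        records = list(sequences)
    return SeqIO.write(records, _as_handle(path), "fasta")


def events_to_frame(events: Sequence[RecombinationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "boundary": [e.boundary for e in events],
            "pathway": [e.pathway.value for e in events],
            "orientation": [e.orientation.value for e in events],
            "outcome": [e.outcome.value for e in events],
            "left_site": [e.left_site for e in events],
            "right_site": [e.right_site for e in events],
        }
    )
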