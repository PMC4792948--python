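"""End-to-end pipeline: simulate -> profile -> infer, with provenance.

Configuration is a flat mapping (typically loaded from YAML) naming the
site, the true crossover boundary of the simulation (or ``"unknown"`` to
use the site's annotated top-strand crossover), sequencing depth per
amplicon class, the substitution error rate, the abnormal-read fraction and
a mandatory seed.  Outputs are deterministic for identical inputs: all
randomness descends from the config seed and the provenance record carries
no timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .crossover_inference import (
    CrossoverCall,
    StringencyReport,
    composite_retained_profile,
    infer_boundary,
    stringency_skew,
)
from .errors import ConfigError
from .seq_pipeline import (
    AnchorSet,
    JunctionProfilePair,
    default_class_anchors,
    discard_log_frame,
    profile_junctions,
    write_profile,
)
from .simulator import (
    DONOR_CONTEXT,
    RECIPIENT_CONTEXT,
    draw_library,
    library_amplicon,
    simulate_cointegrate_pool,
    simulate_reads,
)
from .site_model import (
    DEFAULT_TS_BOUNDARY,
    LibrarySpec,
    SiteModel,
    default_site,
    site_from_dict,
)


def ts_boundary_ordinal(site: SiteModel) -> int:
    """Window-ordinal boundary corresponding to the site's annotated
    top-strand crossover (number of window positions 5' of it)."""
    if site.ts_crossover is None:
        raise ConfigError("site has no annotated ts_crossover")
    return sum(1 for p in site.randomized_window if p <= site.ts_crossover)


@dataclass
class E2EConfig:
    site: SiteModel
    boundary: int
    depth: int = 10_000
    error_rate: float = 0.001
    abnormal_fraction: float = 0.0
    seed: int = 0
    n_events: int | None = None
    error_floor: float | None = None
    expected_nonwt: float | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "E2EConfig":
        problems = []
        d = dict(d)
        site_cfg = d.pop("site", None)
        site = default_site() if site_cfg is None else site_from_dict(site_cfg)
        boundary = d.pop("boundary", "unknown")
        if boundary == "unknown":
            boundary = (ts_boundary_ordinal(site)
                        if site.ts_crossover is not None else DEFAULT_TS_BOUNDARY)
        elif not isinstance(boundary, int) or not 0 <= boundary <= site.P:
            problems.append(f"boundary: must be 'unknown' or an integer in 0..{site.P}")
            boundary = 0
        if "seed" not in d:
            problems.append("seed: required (stochastic steps take no silent entropy)")
        kwargs = {}
        for key, typ, check, msg in (
            ("depth", int, lambda v: v > 0, "must be a positive integer"),
            ("error_rate", float, lambda v: 0 <= v < 1, "must be in [0, 1)"),
            ("abnormal_fraction", float, lambda v: 0 <= v < 1, "must be in [0, 1)"),
            ("seed", int, lambda v: v >= 0, "must be a non-negative integer"),
            ("n_events", int, lambda v: v > 0, "must be a positive integer"),
            ("error_floor", float, lambda v: 0 < v < 1, "must be in (0, 1)"),
            ("expected_nonwt", float, lambda v: 0 < v < 1, "must be in (0, 1)"),
        ):
            if key in d and d[key] is not None:
                try:
                    val = typ(d.pop(key))
                except (TypeError, ValueError):
                    problems.append(f"{key}: {msg}")
                    continue
                if not check(val):
                    problems.append(f"{key}: {msg}")
                else:
                    kwargs[key] = val
            else:
                d.pop(key, None)
        unknown = set(d)
        if unknown:
            problems.append(f"unknown config keys: {sorted(unknown)}")
        if problems:
            raise ConfigError(problems)
        return cls(site=site, boundary=boundary, **kwargs)


@dataclass
class E2EResult:
    call: CrossoverCall
    stringency: StringencyReport
    profiles: JunctionProfilePair
    provenance: dict
    config: E2EConfig = field(repr=False, default=None)


def _config_hash(cfg: E2EConfig) -> str:
    from .site_model import site_to_dict

    doc = {
        "site": site_to_dict(cfg.site),
        "boundary": cfg.boundary,
        "depth": cfg.depth,
        "error_rate": cfg.error_rate,
        "abnormal_fraction": cfg.abnormal_fraction,
        "seed": cfg.seed,
        "n_events": cfg.n_events,
        "error_floor": cfg.error_floor,
        "expected_nonwt": cfg.expected_nonwt,
    }
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_e2e(config: E2EConfig | dict) -> E2EResult:
    """Simulate a crossover-mapping experiment and infer the boundary back.

    Library molecules are drawn, recombined intermolecularly with a
    wild-type partner through the second strand exchange at the configured
    boundary, sequenced (library, left- and right-junction amplicons at
    ``depth`` reads each), classified, filtered, profiled, and the boundary
    is inferred from the junction profile pair; per-position stringency is
    scored on the retained-moiety composite profile.
    """
    if not isinstance(config, E2EConfig):
        config = E2EConfig.from_dict(config)
    site = config.site
    spec = LibrarySpec(site=site)
    seeds = [int(s) for s in
             np.random.SeedSequence(config.seed).generate_state(5) % (2**31 - 1)]
    n_events = config.n_events or config.depth

    molecules = draw_library(spec, n_events, seed=seeds[0])
    pool = simulate_cointegrate_pool(spec, config.boundary, n_events, seed=seeds[1])
    anchors = AnchorSet.from_site(site)
    reads = []
    for templates, seed, prefix in (
        ([library_amplicon(m) for m in molecules], seeds[2], "lib"),
        (pool.left_amplicons, seeds[3], "left"),
        (pool.right_amplicons, seeds[4], "right"),
    ):
        rs = simulate_reads(
            templates,
            depth=config.depth,
            error_rate=config.error_rate,
            abnormal_fraction=config.abnormal_fraction,
            seed=seed,
            anchors=anchors,
            read_id_prefix=prefix,
        )
        reads.extend(rs.records)

    class_anchors = default_class_anchors(DONOR_CONTEXT, RECIPIENT_CONTEXT)
    pair = profile_junctions(reads, site, class_anchors, anchors=anchors)
    error_floor = config.error_floor or max(config.error_rate, 1e-4)
    call = infer_boundary(pair, expected_nonwt=config.expected_nonwt,
                          error_floor=error_floor)
    q = config.expected_nonwt or float(np.mean(pair.library.nonwt_rates()))
    post = composite_retained_profile(pair, call.boundary_hat)
    stringency = stringency_skew(post, expected_nonwt=q)
    provenance = {
        "package": "xovermap",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "boundary_true": config.boundary,
        "boundary_hat": call.boundary_hat,
    }
    return E2EResult(call=call, stringency=stringency, profiles=pair,
                     provenance=provenance, config=config)


def write_results(result: E2EResult, outdir) -> None:
    """Write profiles, call, stringency, discard log and provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_profile(result.profiles.library, outdir / "library_profile.tsv")
    write_profile(result.profiles.left, outdir / "left_profile.tsv")
    write_profile(result.profiles.right, outdir / "right_profile.tsv")
    discard_log_frame(result.profiles.counts).to_csv(
        outdir / "discard_log.tsv", sep="\t", index=False
    )
    with open(outdir / "crossover_call.json", "w") as fh:
        json.dump(result.call.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.stringency.table.to_csv(outdir / "stringency.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    result.stringency.per_base.to_csv(outdir / "stringency_per_base.tsv",
                                      sep="\t", index=False, float_format="%.6g")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
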