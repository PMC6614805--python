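"""Synthetic-data generators for every pipeline input.

Selection-round sequencing reads, gel-elution tables, ITC isotherms and
dye-titration tables can all be generated with known ground truth, so
each analysis stage is testable without any external download.  Every
generator is deterministic under a fixed seed, and each returns a truth
manifest recording the generating parameters and exact spiked counts.

Reads emulate a stem-loop SELEX library: forward primer + 5' stem,
a fixed-length uniformly random loop, 3' stem + reverse primer.  The
real primer/stem sequences are not public, so a synthetic stand-in
design (STANDIN_DESIGN) is shipped and recorded in every manifest.
Base qualities are constant Q30 placeholders (qualities are ignored
downstream); no sequencing-error or PCR-bias model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import DEFAULT_VOLUMES
from .dye import dye_binding_signal
from .itc import (
    ITCExperiment,
    OneSiteParams,
    RacemicParams,
    simulate_isotherm,
)
from .pool import LibraryDesign, ReadSet

__all__ = [
    "STANDIN_DESIGN",
    "PoolSpec",
    "make_pool",
    "make_round_series",
    "make_assay",
    "make_langmuir_assay",
    "make_dye_titration",
    "make_itc_assay",
]

#: Synthetic stand-in library design: 13-nt forward primer + 8-nt stem,
#: 30-nt random loop, complementary 8-nt stem + 14-nt reverse primer
#: (73 nt total).  Not the real library's sequences.
STANDIN_DESIGN = LibraryDesign(
    forward_flank="ATACGAGCTTGTT" + "GGAGGCTC",
    reverse_flank="GAGCCTCC" + "TGGTGTTGGCTCCC",
    random_length=30,
    total_length=73,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class PoolSpec:
    """Recipe for one synthetic selection-round pool.

    families maps a motif (or a full random-region sequence) to the
    fraction of reads it should occupy; the remainder is uniform random
    background.  malformed_fraction of all reads have their reverse
    flank truncated so they fail trimming.
    """

    round_id: str
    n_reads: int
    families: list[tuple[str, float]] = field(default_factory=list)
    design: LibraryDesign = STANDIN_DESIGN
    malformed_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible pools")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        total = sum(f for _, f in self.families)
        if any(f < 0 for _, f in self.families) or total > 1.0:
            raise ValueError("family fractions must be >= 0 and sum to <= 1")
        if not 0.0 <= self.malformed_fraction < 1.0:
            raise ValueError("malformed_fraction must be in [0, 1)")
        for motif, _ in self.families:
            if len(motif) > self.design.random_length:
                raise ValueError("family motif longer than the random region")


def _random_regions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n uniform random DNA strings of the given length, as an (n, length)
    byte matrix."""
    return _BASES[rng.integers(0, 4, size=(n, length))]


def _family_regions(rng: np.random.Generator, n: int, motif: str,
                    length: int) -> np.ndarray:
    """Family-member random regions: the motif embedded at a random offset
    in otherwise-random sequence."""
    regions = _random_regions(rng, n, length)
    mbytes = np.frombuffer(motif.encode(), dtype="S1")
    m = len(motif)
    offsets = rng.integers(0, length - m + 1, size=n)
    for off in np.unique(offsets):
        regions[offsets == off, off : off + m] = mbytes
    return regions


def make_pool(spec: PoolSpec) -> tuple[ReadSet, dict]:
    """Generate one pool of full-length reads plus its truth manifest.

    Category sizes are one multinomial draw over (families...,
    background); family members embed their motif at seeded-random
    offsets.  Malformed reads (seeded choice, without replacement) lose
    the last 10 nt covering the reverse flank, so they are discarded at
    trimming.  The manifest records per-family spiked and well-formed
    counts — downstream family fractions over kept reads can be checked
    against it exactly.
    """
    rng = np.random.default_rng(spec.seed)
    design = spec.design
    length = design.random_length
    fracs = [f for _, f in spec.families]
    probs = fracs + [1.0 - sum(fracs)]
    sizes = rng.multinomial(spec.n_reads, probs)

    blocks = []
    labels = []
    for (motif, _), k in zip(spec.families, sizes[:-1]):
        if k:
            if len(motif) == length:
                block = np.tile(np.frombuffer(motif.encode(), dtype="S1"),
                                (k, 1))
            else:
                block = _family_regions(rng, k, motif, length)
            blocks.append(block)
        labels += [motif] * k
    n_bg = sizes[-1]
    if n_bg:
        blocks.append(_random_regions(rng, n_bg, length))
    labels += ["background"] * n_bg
    regions = np.concatenate(blocks, axis=0)

    order = rng.permutation(spec.n_reads)
    regions = regions[order]
    labels = np.asarray(labels, dtype=object)[order]

    n_bad = int(round(spec.malformed_fraction * spec.n_reads))
    bad = np.zeros(spec.n_reads, dtype=bool)
    if n_bad:
        bad[rng.choice(spec.n_reads, size=n_bad, replace=False)] = True

    ff, rf = design.forward_flank, design.reverse_flank
    region_strs = regions.view(f"S{length}").ravel().astype(str)
    qual_full = "?" * design.total_length  # constant Q30 placeholder
    records = []
    for i, region in enumerate(region_strs):
        seq = ff + region + rf
        if bad[i]:
            seq = seq[:-10]
        records.append((f"{spec.round_id}_read{i}", seq,
                        qual_full[: len(seq)]))

    family_counts = {
        motif: int(k) for (motif, _), k in zip(spec.families, sizes[:-1])
    }
    wellformed = {
        motif: int(np.sum((labels == motif) & ~bad))
        for motif, _ in spec.families
    }
    manifest = {
        "round_id": spec.round_id,
        "n_reads": spec.n_reads,
        "seed": spec.seed,
        "design": {
            "forward_flank": ff,
            "reverse_flank": rf,
            "random_length": length,
            "total_length": design.total_length,
        },
        "family_counts": family_counts,
        "family_counts_wellformed": wellformed,
        "n_malformed": int(n_bad),
        "n_wellformed": int(spec.n_reads - n_bad),
        "background_model": "uniform iid",
    }
    return ReadSet(pool_id=spec.round_id, records=records), manifest


def make_round_series(specs: list[PoolSpec]) -> tuple[list[ReadSet], dict]:
    """One pool per selection round, with a combined trajectory manifest."""
    if not specs:
        raise ValueError("need at least one round spec")
    pools, manifests = [], []
    for spec in specs:
        reads, manifest = make_pool(spec)
        pools.append(reads)
        manifests.append(manifest)
    truth = {
        "rounds": [m["round_id"] for m in manifests],
        "per_round": manifests,
        "target_fractions": [
            dict(spec.families) for spec in specs
        ],
    }
    return pools, truth


def make_langmuir_assay(
    kd: float,
    theta_max: float,
    concs: list[float] | np.ndarray = (0, 10, 50, 100, 250, 500, 1000),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Gel-elution curve theta(c) from a Langmuir isotherm.

    The expectation is computed from the closed form (independent of any
    fitting code); Gaussian noise of the stated SD (fraction units) is
    added when requested.  Returns (concs, thetas as fractions, truth).
    """
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    c = np.asarray(concs, dtype=float)
    theta = theta_max * c / (kd + c)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        theta = np.clip(theta + rng.normal(0, noise_sd, size=len(c)), 0.0, 1.6)
    truth = {"model": "langmuir", "kd_uM": kd, "theta_max": theta_max,
             "noise_sd": noise_sd, "seed": seed,
             "volumes_ul": DEFAULT_VOLUMES}
    return c, theta, truth


def make_dye_titration(
    kd: float,
    dye_conc: float,
    aptamer_concs: list[float] | np.ndarray,
    signal_free: float = 0.05,
    signal_bound: float = 0.60,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Aptamer-into-dye titration readout from the exact quadratic isotherm."""
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    a = np.asarray(aptamer_concs, dtype=float)
    y = dye_binding_signal(a, dye_conc, kd, signal_free, signal_bound)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0, noise_sd, size=len(a))
    truth = {"model": "dye_displacement", "kd_uM": kd, "dye_conc_uM": dye_conc,
             "signal_free": signal_free, "signal_bound": signal_bound,
             "noise_sd": noise_sd, "seed": seed}
    return a, y, truth


def make_itc_assay(
    params: OneSiteParams | RacemicParams,
    exp: ITCExperiment,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[object, dict]:
    """Simulated ITC isotherm plus a truth manifest of its parameters."""
    iso = simulate_isotherm(params, exp, noise_sd=noise_sd, seed=seed)
    truth = {
        "model": "one_site_itc" if isinstance(params, OneSiteParams)
        else "racemic_itc",
        "params": params.__dict__ | {},
        "experiment": {
            "cell_volume_ul": exp.cell_volume,
            "cell_conc_uM": exp.cell_conc,
            "syringe_conc_uM": exp.syringe_conc,
            "injection_volumes_ul": list(exp.injection_volumes),
            "temperature_K": exp.temperature,
        },
        "noise_sd_uJ": noise_sd,
        "seed": seed,
    }
    return iso, truth


_ASSAY_MAKERS = {
    "langmuir": make_langmuir_assay,
    "one_site_itc": make_itc_assay,
    "racemic_itc": make_itc_assay,
    "dye_displacement": make_dye_titration,
}


def make_assay(model: str, **kwargs):
    """Dispatch to the named assay generator.

    ``model`` is one of 'langmuir', 'one_site_itc', 'racemic_itc' or
    'dye_displacement'; keyword arguments are forwarded unchanged.
    """
    try:
        maker = _ASSAY_MAKERS[model]
    except KeyError:
        raise ValueError(
            f"unknown assay model {model!r}; expected one of "
            f"{sorted(_ASSAY_MAKERS)}"
        ) from None
    return maker(**kwargs)
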