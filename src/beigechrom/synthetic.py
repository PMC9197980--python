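"""Synthetic snATAC-seq cohorts and lipid tables with known ground truth.

The generator emulates the structure of a combinatorial-indexing snATAC-seq
study of adipose beiging: seven treatment groups (day-0 room temperature,
then cold or beta3-agonist at days 1/3/7), three replicate animals per
group, sparse near-binary per-cell accessibility over planted peaks with
cell-type-specific accessible sets, log-normal per-cell sequencing depth,
barcode collisions formed by pooling random same-sample cell pairs, and a
beige adipocyte population that grows from ~1% to ~5% of cells under
treatment. Lipid (FAME) tables carry group-dependent linear day trends.

All randomness flows through one ``numpy.random.Generator`` created from an
explicit seed; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .lipids import LipidTable, parse_species

BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Simulation design references unknown entities or is inconsistent."""


@dataclass
class GenomeModel:
    """A small random genome with a blacklist.

    ``sequence`` maps chromosome name to an A/C/G/T string whose length
    equals the declared chromosome length. Blacklist intervals are 0-based
    half-open and must lie within chromosome bounds.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequence: dict[str, str]
    blacklist: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        for chrom in self.chrom_names:
            if len(self.sequence[chrom]) != self.chrom_lengths[chrom]:
                raise ConfigurationError(f"sequence length mismatch on {chrom}")
        for row in self.blacklist.itertuples():
            if not (0 <= row.start < row.end <= self.chrom_lengths[row.chrom]):
                raise ConfigurationError("blacklist interval outside chromosome bounds")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequence[chrom][start:end]


@dataclass
class RegulatoryTruth:
    """Planted peaks, cell types, and the activity table tying them together.

    ``activity`` is a cell_type x peak DataFrame of accessibility
    probabilities in [0, 1]; ``peaks`` carries an ``owner`` cell type and an
    optional planted ``motif`` id per peak; ``beige_trajectory`` maps day to
    the target beige fraction and must be monotone non-decreasing.
    """

    peaks: pd.DataFrame  # chrom, start, end, owner, motif
    cell_types: list[str]
    activity: pd.DataFrame
    beige_trajectory: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = self.activity.to_numpy()
        if (a < 0).any() or (a > 1).any():
            raise ConfigurationError("activity probabilities must lie in [0, 1]")
        days = sorted(self.beige_trajectory)
        fracs = [self.beige_trajectory[d] for d in days]
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ConfigurationError("beige trajectory must be monotone in day")


@dataclass
class SampleSpec:
    sample: str
    condition: str  # RT, cold, or CL
    day: int
    replicate: int
    n_cells: int
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigurationError(f"proportions for {self.sample} sum to {total}, not 1")


DEFAULT_CELL_TYPES = [
    "white_adipocyte", "beige_adipocyte", "macrophage", "dendritic",
    "tcell", "apc", "vec", "vsmc",
]

# Day-0 composition: ~22% adipocytes, ~72% immune, ~3% progenitors, ~3% stromal.
BASE_PROPORTIONS = {
    "white_adipocyte": 0.21, "beige_adipocyte": 0.01,
    "macrophage": 0.35, "dendritic": 0.15, "tcell": 0.22,
    "apc": 0.03, "vec": 0.02, "vsmc": 0.01,
}

DEFAULT_BEIGE_TRAJECTORY = {0: 0.01, 1: 0.017, 3: 0.03, 7: 0.05}

# Distinctive 12-mer consensus sequences planted into type-specific peaks,
# loosely shaped after nuclear-receptor and ETS-family sites.
DEFAULT_MOTIF_CONSENSUS = {
    "M_BEIGE": "TGACCTTGACCT",
    "M_WHITE": "AGGTCAAAGGTC",
    "M_MACRO": "ACAGGAAGTGAG",
    "M_TCELL": "TTCCCAGGAAGT",
    "M_APC": "CACGTGACCACA",
}

DEFAULT_MOTIF_BY_TYPE = {
    "beige_adipocyte": "M_BEIGE",
    "white_adipocyte": "M_WHITE",
    "macrophage": "M_MACRO",
    "tcell": "M_TCELL",
    "apc": "M_APC",
}


def default_design(
    n_cells_per_sample: int = 500,
    n_replicates: int = 3,
    beige_trajectory: dict[int, float] | None = None,
    cell_types: list[str] | None = None,
) -> list[SampleSpec]:
    """The study's seven groups x replicates with a growing beige fraction.

    Groups: day0 RT, then cold and CL at days 1, 3, 7. The beige fraction
    follows ``beige_trajectory`` under treatment (RT stays at day-0 level);
    growth is taken out of the white adipocyte share so the immune,
    progenitor, and stromal fractions stay fixed.
    """
    traj = dict(DEFAULT_BEIGE_TRAJECTORY if beige_trajectory is None else beige_trajectory)
    types = list(DEFAULT_CELL_TYPES if cell_types is None else cell_types)
    groups = [("RT", 0)] + [(cond, day) for cond in ("cold", "CL") for day in (1, 3, 7)]
    design = []
    for cond, day in groups:
        beige = traj[day] if cond != "RT" else traj[min(traj)]
        props = dict(BASE_PROPORTIONS)
        delta = beige - props["beige_adipocyte"]
        props["beige_adipocyte"] = beige
        props["white_adipocyte"] -= delta
        props = {t: props[t] for t in types}
        for rep in range(1, n_replicates + 1):
            design.append(SampleSpec(
                sample=f"day{day}{cond}_r{rep}", condition=cond, day=day,
                replicate=rep, n_cells=n_cells_per_sample, proportions=props,
            ))
    return design


def make_genome(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int] | None = None,
    gc: float = 0.42,
    n_blacklist: int = 4,
    blacklist_width: int = 20_000,
) -> GenomeModel:
    """Random genome (default two 5-Mb chromosomes) with a small blacklist."""
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 5_000_000, "chr2": 5_000_000}
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequence = {
        chrom: "".join(BASES[rng.choice(4, size=length, p=p)])
        for chrom, length in chrom_lengths.items()
    }
    rows = []
    chroms = list(chrom_lengths)
    for _ in range(n_blacklist):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_lengths[chrom] - blacklist_width))
        rows.append((chrom, start, start + blacklist_width))
    blacklist = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return GenomeModel(chroms, dict(chrom_lengths), sequence, blacklist)


def make_truth(
    genome: GenomeModel,
    rng: np.random.Generator,
    cell_types: list[str] | None = None,
    n_peaks: int = 400,
    peak_width: int = 500,
    min_gap: int = 5_000,
    specific_activity: float = 0.85,
    background_activity: float = 0.02,
    shared_fraction: float = 0.3,
    shared_activity: float = 0.5,
    motif_by_type: dict[str, str] | None = None,
    motif_consensus: dict[str, str] | None = None,
    plant_motifs: bool = True,
) -> RegulatoryTruth:
    """Plant fixed-width peaks >= ``min_gap`` apart and assign type activity.

    A ``shared_fraction`` of peaks is accessible in every type (housekeeping
    regions); the rest are owned by one cell type (round-robin) and highly
    accessible only there. When ``plant_motifs`` each owned peak of a type
    with a motif gets that motif's consensus written at the peak centre
    (mutating the genome sequence), so motif scanning has a ground truth.
    """
    types = list(DEFAULT_CELL_TYPES if cell_types is None else cell_types)
    if motif_by_type is None:
        motif_by_type = {t: m for t, m in DEFAULT_MOTIF_BY_TYPE.items() if t in types}
    if motif_consensus is None:
        motif_consensus = DEFAULT_MOTIF_CONSENSUS
    # lay peaks on a grid with jitter; slot width absorbs the jitter so the
    # inter-peak gap stays >= min_gap
    jitter = min_gap // 2
    slot = peak_width + min_gap + jitter
    positions = []
    for chrom, length in genome.chrom_lengths.items():
        n_slots = (length - min_gap) // slot
        for i in range(n_slots):
            start = min_gap + i * slot + int(rng.integers(0, jitter))
            if start + peak_width <= length:
                positions.append((chrom, start, start + peak_width))
    if len(positions) < n_peaks:
        raise ConfigurationError(
            f"genome too small for {n_peaks} peaks with gap {min_gap}"
        )
    pick = rng.choice(len(positions), size=n_peaks, replace=False)
    pick.sort()
    peaks = pd.DataFrame(
        [positions[i] for i in pick], columns=["chrom", "start", "end"]
    )
    n_shared = int(round(shared_fraction * n_peaks))
    owner = ["shared"] * n_shared + [
        types[i % len(types)] for i in range(n_peaks - n_shared)
    ]
    rng.shuffle(owner)
    peaks["owner"] = owner
    activity = pd.DataFrame(
        background_activity, index=types, columns=range(n_peaks), dtype=float
    )
    for j, own in enumerate(owner):
        if own == "shared":
            activity.loc[:, j] = shared_activity
        else:
            activity.loc[own, j] = specific_activity
    peaks["motif"] = [
        motif_by_type.get(own, "") if own != "shared" else "" for own in owner
    ]
    if plant_motifs:
        seqs = {c: list(genome.sequence[c]) for c in genome.chrom_names}
        for row in peaks.itertuples():
            if not row.motif:
                continue
            cons = motif_consensus[row.motif]
            mid = (row.start + row.end) // 2 - len(cons) // 2
            seqs[row.chrom][mid:mid + len(cons)] = list(cons)
        genome.sequence = {c: "".join(s) for c, s in seqs.items()}
    for m in peaks["motif"]:
        if m and m not in motif_consensus:
            raise ConfigurationError(f"planted motif {m!r} has no consensus")
    return RegulatoryTruth(peaks, types, activity, dict(DEFAULT_BEIGE_TRAJECTORY))


def simulate_atac(
    design: list[SampleSpec] | None = None,
    genome: GenomeModel | None = None,
    truth: RegulatoryTruth | None = None,
    depth_lognormal: tuple[float, float] = (8.0, 0.6),
    collision_rate: float = 0.0,
    fragment_length: tuple[float, float] = (180.0, 40.0),
    seed: int = 0,
):
    """Simulate a fragment file with known per-cell truth.

    Per cell, the fragment count is log-normal(``mu``, ``sigma``). Each
    fragment picks a planted peak uniformly at random and lands inside it
    with probability ``activity[cell_type, peak]``; otherwise it falls
    uniformly on the genome. Barcode collisions pool the fragments of two
    randomly paired same-sample cells under one new barcode, so a
    ``collision_rate`` fraction of the observed barcodes are collisions.

    Returns ``(genome, truth, fragments, cell_truth)`` where ``cell_truth``
    has one row per observed barcode with columns barcode, sample,
    condition, day, replicate, true_type, n_fragments, is_collision,
    parent_barcodes, parent_types.
    """
    if not 0 <= collision_rate <= 0.5:
        raise ConfigurationError("collision_rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    if genome is None:
        genome = make_genome(rng)
    if truth is None:
        truth = make_truth(genome, rng)
    if design is None:
        design = default_design()
    for spec in design:
        unknown = set(spec.proportions) - set(truth.cell_types)
        if unknown:
            raise ConfigurationError(f"design references unknown cell types {unknown}")

    mu, sigma = depth_lognormal
    flen_mu, flen_sd = fragment_length
    peaks = truth.peaks
    n_peaks = len(peaks)
    peak_chrom = peaks["chrom"].to_numpy()
    peak_start = peaks["start"].to_numpy()
    peak_width = (peaks["end"] - peaks["start"]).to_numpy()
    chrom_names = genome.chrom_names
    chrom_len = np.array([genome.chrom_lengths[c] for c in chrom_names])
    chrom_offset = np.concatenate([[0], np.cumsum(chrom_len)])
    total_len = int(chrom_offset[-1])
    act = truth.activity.loc[truth.cell_types].to_numpy()
    type_index = {t: i for i, t in enumerate(truth.cell_types)}
    chrom_of_peak = np.array([chrom_names.index(c) for c in peak_chrom])

    frag_frames = []
    truth_rows = []
    for spec in design:
        n_coll = int(round(collision_rate * spec.n_cells))
        n_latent = spec.n_cells + n_coll  # n_cells - n_coll singlets + 2*n_coll parents
        props = np.array([spec.proportions.get(t, 0.0) for t in truth.cell_types])
        latent_types = rng.choice(len(truth.cell_types), size=n_latent, p=props)
        depths = np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n_latent))).astype(np.int64)

        # latent cell -> observed barcode assignment
        perm = rng.permutation(n_latent)
        singlets = perm[: spec.n_cells - n_coll]
        paired = perm[spec.n_cells - n_coll:].reshape(n_coll, 2)
        obs_of_latent = np.empty(n_latent, dtype=np.int64)
        obs_of_latent[singlets] = np.arange(spec.n_cells - n_coll)
        for k in range(n_coll):
            obs_of_latent[paired[k]] = spec.n_cells - n_coll + k
        obs_names = np.array(
            [f"{spec.sample}_BC{i:05d}" for i in range(spec.n_cells)]
        )

        # vectorised fragment placement for all latent cells of this sample
        n_frag = int(depths.sum())
        cell_of_frag = np.repeat(np.arange(n_latent), depths)
        type_of_frag = latent_types[cell_of_frag]
        peak_pick = rng.integers(0, n_peaks, size=n_frag)
        in_peak = rng.random(n_frag) < act[type_of_frag, peak_pick]
        flen = np.clip(
            np.round(rng.normal(flen_mu, flen_sd, size=n_frag)), 50, 400
        ).astype(np.int64)
        start = np.empty(n_frag, dtype=np.int64)
        chrom_idx = np.empty(n_frag, dtype=np.int64)
        # in-peak fragments: contained in the picked peak
        pk = peak_pick[in_peak]
        room = np.maximum(peak_width[pk] - flen[in_peak], 1)
        start[in_peak] = peak_start[pk] + (rng.random(in_peak.sum()) * room).astype(np.int64)
        chrom_idx[in_peak] = chrom_of_peak[pk]
        # background fragments: uniform over the concatenated genome
        n_bg = int((~in_peak).sum())
        gpos = rng.integers(0, total_len - 500, size=n_bg)
        cix = np.searchsorted(chrom_offset, gpos, side="right") - 1
        chrom_idx[~in_peak] = cix
        start[~in_peak] = gpos - chrom_offset[cix]
        end = np.minimum(start + flen, chrom_len[chrom_idx])
        frag_frames.append(pd.DataFrame({
            "chrom": np.array(chrom_names)[chrom_idx],
            "start": start,
            "end": end,
            "barcode": obs_names[obs_of_latent[cell_of_frag]],
        }))

        type_names = np.array(truth.cell_types)
        for i in singlets:
            truth_rows.append((
                obs_names[obs_of_latent[i]], spec.sample, spec.condition,
                spec.day, spec.replicate, type_names[latent_types[i]],
                int(depths[i]), False, "", "",
            ))
        for k in range(n_coll):
            a, b = paired[k]
            truth_rows.append((
                obs_names[spec.n_cells - n_coll + k], spec.sample,
                spec.condition, spec.day, spec.replicate, "collision",
                int(depths[a] + depths[b]), True,
                f"latent{a}|latent{b}",
                f"{type_names[latent_types[a]]}+{type_names[latent_types[b]]}",
            ))

    fragments = FragmentSet(pd.concat(frag_frames, ignore_index=True))
    cell_truth = pd.DataFrame(truth_rows, columns=[
        "barcode", "sample", "condition", "day", "replicate", "true_type",
        "n_fragments", "is_collision", "parent_barcodes", "parent_types",
    ]).sort_values("barcode").reset_index(drop=True)
    return genome, truth, fragments, cell_truth


def simulate_lipids(
    groups: pd.DataFrame,
    base_percentages: dict[str, float],
    slopes: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LipidTable:
    """Per-sample FAME percentage tables with linear day trends.

    ``groups`` needs columns sample, condition, day. ``slopes`` maps
    condition -> {species: percentage points per day}. Each sample's species
    percentage is base + slope*day + N(0, noise_sd), clipped at 0 and
    renormalised to sum to 100. Species names must parse as C:Dn-x.
    """
    for name in base_percentages:
        parse_species(name)  # raises on malformed names
    total = sum(base_percentages.values())
    if abs(total - 100.0) > 1e-6:
        raise ConfigurationError(f"base percentages sum to {total}, not 100")
    slopes = slopes or {}
    rng = np.random.default_rng(seed)
    species = list(base_percentages)
    rows = []
    for row in groups.itertuples():
        cond_slopes = slopes.get(row.condition, {})
        vals = np.array([
            base_percentages[s] + cond_slopes.get(s, 0.0) * row.day
            for s in species
        ])
        vals = vals + rng.normal(0.0, noise_sd, size=len(species))
        vals = np.clip(vals, 0.0, None)
        vals = vals / vals.sum() * 100.0
        rows.append(vals)
    table = pd.DataFrame(rows, columns=species, index=pd.Index(groups["sample"], name="sample"))
    return LipidTable(table, metadata=groups.reset_index(drop=True))


def simulate_coaccess_cells(
    n_cells: int = 2_000,
    n_pairs: int = 15,
    n_singletons: int = 30,
    spacing: int = 15_000,
    peak_width: int = 500,
    mu_on: float = 4.0,
    mu_off: float = 0.2,
    p_active: float = 0.5,
    seed: int = 0,
):
    """Cells with planted co-regulated peak pairs for link inference tests.

    Peaks sit every ``spacing`` bp on one chromosome. Each planted pair
    shares a per-cell Bernoulli activity state (both members draw counts
    from ``mu_on`` when active, ``mu_off`` otherwise); singleton peaks have
    independent states. Pair members land at random genomic slots, so
    planted and independent pairs span comparable distances.

    Returns ``(FeatureMatrix, pairs)`` with ``pairs`` rows (peak_a, peak_b)
    as feature row indices.
    """
    from .fragments import FeatureMatrix

    rng = np.random.default_rng(seed)
    n_peaks = 2 * n_pairs + n_singletons
    # place pair members within ~25 slots of each other so planted pairs
    # stay inside a typical co-accessibility window; singletons anywhere
    slots = np.full(n_peaks, -1, dtype=int)
    free = list(range(n_peaks))
    rng.shuffle(free)
    free_set = set(free)
    for k in range(n_pairs):
        for a in free:
            if a not in free_set:
                continue
            choices = [b for b in free_set if b != a and 2 <= abs(b - a) <= 25]
            if choices:
                b = choices[rng.integers(len(choices))]
                slots[2 * k], slots[2 * k + 1] = a, b
                free_set.discard(a)
                free_set.discard(b)
                break
        else:
            raise ConfigurationError("could not place all planted pairs")
    rest = sorted(free_set)
    rng.shuffle(rest)
    slots[2 * n_pairs:] = rest
    starts = spacing + np.arange(n_peaks) * spacing
    feats = pd.DataFrame({
        "chrom": "chr1",
        "start": starts,
        "end": starts + peak_width,
    })
    # latent activity per cell: one column per pair, one per singleton
    n_latent = n_pairs + n_singletons
    active = rng.random((n_cells, n_latent)) < p_active
    latent_of_peak = np.concatenate([
        np.repeat(np.arange(n_pairs), 2), n_pairs + np.arange(n_singletons)
    ])
    mu = np.where(active[:, latent_of_peak], mu_on, mu_off)
    counts = rng.poisson(mu)
    # scatter peaks over genomic slots
    counts_slotted = np.zeros_like(counts)
    counts_slotted[:, slots] = counts
    barcodes = np.array([f"CELL{i:05d}" for i in range(n_cells)])
    fm = FeatureMatrix(
        np.asarray(counts_slotted, dtype=float), barcodes,
        np.array([f"chr1:{s}-{s + peak_width}" for s in starts]), feats,
    )
    pair_rows = [
        (int(slots[2 * k]), int(slots[2 * k + 1])) for k in range(n_pairs)
    ]
    pairs = pd.DataFrame(
        [(min(a, b), max(a, b)) for a, b in pair_rows], columns=["peak_a", "peak_b"]
    )
    return fm, pairs


def write_fasta(genome: GenomeModel, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
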