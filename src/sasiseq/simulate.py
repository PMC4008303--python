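"""Seeded synthetic library generator for spike-in assurance experiments.

Emulates the wet-lab path of a spiked sample at desk scale: a genome plus
barcoded spike-in fragments dosed by mass fraction, acoustic shearing to a
target mean size (Gamma-renewal breakpoint model), size selection, and
paired-end
sequencing with iid per-base substitution error and an index read.  Swap and
contamination events can be injected so that downstream screening can be
validated against a complete per-read truth table.

A fast count-level mode draws spike-in read counts directly from binomials
for power studies that do not need base-level realism.
"""

from __future__ import annotations

import gzip as gzip_mod
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .barcodes import Barcode
from .spikein import SASISet, revcomp

__all__ = [
    "ShearModel",
    "SizeSelection",
    "ReadSimConfig",
    "SyntheticSample",
    "ContaminationEvent",
    "SwapEvent",
    "MoleculePool",
    "ReadBatch",
    "ExperimentResult",
    "random_genome",
    "shear_molecules",
    "size_select",
    "simulate_reads",
    "simulate_experiment",
    "count_level_simulate",
]


def random_genome(length: int, seed: int = 1, gc: float = 0.5) -> str:
    """Uniform-composition random genome; a neutral stand-in for sample DNA."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


@dataclass(frozen=True)
class ShearModel:
    """Acoustic-shearing surrogate: breakpoints placed by a Gamma renewal
    process along each molecule.

    Cut spacings are drawn iid from Gamma(shape=1/dispersion^2,
    mean=target_mean_size), so fragment lengths are unimodal around the
    target mean with coefficient of variation ``dispersion`` — the behaviour
    of focused acoustic shearing, which concentrates sizes around the dialed
    mean rather than producing the size-zero mode of a uniform breakage
    process.  Molecules much shorter than the target mean rarely receive a
    cut; much longer ones are cut into ~length/mean pieces.  ``dispersion``
    of 0 degenerates to deterministic cutting at exact multiples of the mean.
    """

    target_mean_size: float
    dispersion: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.target_mean_size <= 0:
            raise ValueError("target_mean_size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class SizeSelection:
    """Retention window in bp.  ``edge_steepness`` is the bp scale of a
    logistic roll-off at each edge; 0 keeps exactly lower <= len <= upper."""

    lower: int
    upper: int
    edge_steepness: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("size window must satisfy lower < upper")


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 75
    paired: bool = True
    per_base_error: float = 0.01
    total_reads: int = 100_000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not (0.0 <= self.per_base_error <= 1.0):
            raise ValueError("per_base_error must lie in [0,1]")


@dataclass
class SyntheticSample:
    """A sample's material: genome, spike-in sets with mass fractions, and
    the library (index) barcode attached during library prep."""

    sample_id: str
    genome: str
    sasi_sets: list[tuple[SASISet, float]]
    library_barcode: Barcode

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.sasi_sets)
        if any(f < 0 or f > 1 for _, f in self.sasi_sets) or total >= 1:
            raise ValueError("spike mass fractions must lie in [0,1] and sum below 1")


@dataclass(frozen=True)
class ContaminationEvent:
    """Source material mixed into recipient before library prep, at
    ``relative_fraction`` of the recipient's concentration."""

    recipient_sample: str
    source_sample: str
    relative_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.relative_fraction <= 1.0):
            raise ValueError("relative_fraction must lie in (0,1]")


@dataclass(frozen=True)
class SwapEvent:
    """Two tubes transposed after spiking: library barcodes follow the tube
    position, spike-ins follow the sample material."""

    sample_a: str
    sample_b: str

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError("a swap needs two distinct samples")


# ---------------------------------------------------------------------------
# molecule pools


class MoleculePool:
    """A weighted pool of molecules, each a slice of a parent sequence.

    ``weight`` is a molecule count (may be fractional: a weight of 0.25
    means this realization stands for a quarter molecule in expectation);
    read sampling is proportional to weight (molar).  ``origin`` labels the
    molecule's provenance; ``intact`` records whether it still spans its
    original parent end-to-end.
    """

    def __init__(
        self,
        parents: list[str],
        parent_idx: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        weight: np.ndarray,
        origin_idx: np.ndarray,
        origins: list[str],
        intact: np.ndarray,
    ):
        self.parents = parents
        self.parent_idx = parent_idx.astype(np.int32)
        self.start = start.astype(np.int64)
        self.end = end.astype(np.int64)
        self.weight = weight.astype(np.float64)
        self.origin_idx = origin_idx.astype(np.int32)
        self.origins = origins
        self.intact = intact.astype(bool)

    @classmethod
    def from_molecules(cls, molecules: Iterable[tuple[str, float, str]]) -> "MoleculePool":
        """Build from (sequence, weight, origin_label) triples."""
        parents, pidx, starts, ends, weights, oidx = [], [], [], [], [], []
        origins: list[str] = []
        omap: dict[str, int] = {}
        for seq, w, label in molecules:
            if not seq:
                raise ValueError("empty molecule sequence")
            if label not in omap:
                omap[label] = len(origins)
                origins.append(label)
            pidx.append(len(parents))
            parents.append(seq)
            starts.append(0)
            ends.append(len(seq))
            weights.append(w)
            oidx.append(omap[label])
        if not parents:
            raise ValueError("molecule pool is empty")
        n = len(parents)
        return cls(
            parents,
            np.array(pidx),
            np.array(starts),
            np.array(ends),
            np.array(weights),
            np.array(oidx),
            origins,
            np.ones(n, dtype=bool),
        )

    def __len__(self) -> int:
        return len(self.parent_idx)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def total_bases(self) -> float:
        """Weighted base count (mass in base units)."""
        return float((self.lengths * self.weight).sum())

    def sequence(self, i: int) -> str:
        return self.parents[self.parent_idx[i]][self.start[i] : self.end[i]]

    def subset(self, mask: np.ndarray) -> "MoleculePool":
        return MoleculePool(
            self.parents,
            self.parent_idx[mask],
            self.start[mask],
            self.end[mask],
            self.weight[mask],
            self.origin_idx[mask],
            self.origins,
            self.intact[mask],
        )

    def scaled(self, factor: float, origin_prefix: str = "") -> "MoleculePool":
        """Copy with weights multiplied by ``factor`` and origins optionally
        re-labelled with a prefix (used for contamination provenance)."""
        origins = [origin_prefix + o for o in self.origins] if origin_prefix else self.origins
        return MoleculePool(
            self.parents,
            self.parent_idx.copy(),
            self.start.copy(),
            self.end.copy(),
            self.weight * factor,
            self.origin_idx.copy(),
            list(origins),
            self.intact.copy(),
        )

    @staticmethod
    def concat(pools: Sequence["MoleculePool"]) -> "MoleculePool":
        parents: list[str] = []
        origins: list[str] = []
        omap: dict[str, int] = {}
        parts = []
        for pool in pools:
            p_off = len(parents)
            parents.extend(pool.parents)
            remap = np.empty(len(pool.origins), dtype=np.int32)
            for k, label in enumerate(pool.origins):
                if label not in omap:
                    omap[label] = len(origins)
                    origins.append(label)
                remap[k] = omap[label]
            parts.append(
                (
                    pool.parent_idx + p_off,
                    pool.start,
                    pool.end,
                    pool.weight,
                    remap[pool.origin_idx],
                    pool.intact,
                )
            )
        return MoleculePool(
            parents,
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
            np.concatenate([p[2] for p in parts]),
            np.concatenate([p[3] for p in parts]),
            np.concatenate([p[4] for p in parts]),
            origins,
            np.concatenate([p[5] for p in parts]),
        )


def _cut_positions(
    length: int, mean: float, dispersion: float, rng: np.random.Generator
) -> list[int]:
    """Breakpoint offsets (exclusive of 0 and length) for one molecule,
    drawn as the partial sums of Gamma-distributed spacings."""
    if length < 2:
        return []
    if dispersion == 0.0:
        step = int(round(mean))
        return list(range(step, length, step)) if step < length else []
    shape = 1.0 / dispersion**2
    scale = mean / shape
    cuts: list[int] = []
    pos = 0.0
    # draw spacings in batches; expected count is length/mean
    batch = max(4, int(length / mean * 1.5) + 8)
    while True:
        for g in rng.gamma(shape, scale, size=batch):
            pos += g
            if pos >= length:
                return cuts
            c = int(pos)
            if 0 < c < length and (not cuts or c > cuts[-1]):
                cuts.append(c)
        batch = 8


def shear_molecules(pool: MoleculePool, model: ShearModel) -> MoleculePool:
    """Cut every molecule at Gamma-renewal breakpoints (see
    :class:`ShearModel`).

    The children partition the parent exactly, so bases are conserved; the
    outcome is deterministic for the model's seed.
    """
    rng = np.random.default_rng(model.seed)

    pidx, starts, ends, weights, oidx, intact = [], [], [], [], [], []
    for i in range(len(pool)):
        s, e = int(pool.start[i]), int(pool.end[i])
        cuts = [s + c for c in _cut_positions(e - s, model.target_mean_size, model.dispersion, rng)]
        bounds = [s] + cuts + [e]
        whole = len(bounds) == 2
        for a, b in zip(bounds[:-1], bounds[1:]):
            pidx.append(pool.parent_idx[i])
            starts.append(a)
            ends.append(b)
            weights.append(pool.weight[i])
            oidx.append(pool.origin_idx[i])
            intact.append(bool(pool.intact[i]) and whole)
    return MoleculePool(
        pool.parents,
        np.array(pidx),
        np.array(starts),
        np.array(ends),
        np.array(weights),
        np.array(oidx),
        pool.origins,
        np.array(intact),
    )


def size_select(pool: MoleculePool, window: SizeSelection) -> MoleculePool:
    """Retain fragments by length: a hard window when edge_steepness is 0, a
    seeded logistic roll-off at each edge otherwise."""
    lengths = pool.lengths
    if window.edge_steepness == 0:
        keep = (lengths >= window.lower) & (lengths <= window.upper)
    else:
        s = window.edge_steepness
        p_lo = 1.0 / (1.0 + np.exp(-(lengths - window.lower) / s))
        p_hi = 1.0 / (1.0 + np.exp(-(window.upper - lengths) / s))
        rng = np.random.default_rng(window.seed)
        keep = rng.random(len(pool)) < p_lo * p_hi
    return pool.subset(keep)


# ---------------------------------------------------------------------------
# sequencing


_ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII_TO_CODE[_b] = _i
_CODE_TO_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seqs: list[str], p: float, rng: np.random.Generator) -> list[str]:
    """Apply iid per-base substitution (uniform over the 3 alternatives) to a
    batch of sequences via one concatenated byte buffer."""
    if p == 0.0 or not seqs:
        return seqs
    joined = "".join(seqs).encode("ascii")
    arr = np.frombuffer(joined, dtype=np.uint8).copy()
    codes = _ASCII_TO_CODE[arr]
    hit = (rng.random(len(arr)) < p) & (codes < 4)
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
        arr[hit] = _CODE_TO_ASCII[codes[hit]]
    out = arr.tobytes().decode("ascii")
    res = []
    pos = 0
    for s in seqs:
        res.append(out[pos : pos + len(s)])
        pos += len(s)
    return res


@dataclass
class ReadBatch:
    """Simulated reads from one demultiplexed library (tube)."""

    read_ids: list[str]
    r1: list[str]
    r2: list[str] | None
    index: list[str]
    origin: list[str]  # provenance label of the source molecule
    from_intact: np.ndarray  # source molecule spanned its parent end-to-end

    def __len__(self) -> int:
        return len(self.r1)


def simulate_reads(
    pool: MoleculePool,
    config: ReadSimConfig,
    library_barcode: Barcode,
    id_prefix: str = "read",
    rng: np.random.Generator | None = None,
) -> ReadBatch:
    """Sample reads with replacement proportional to molecule weight (molar).

    Read 1 is the fragment 5' prefix; read 2 (if paired) the reverse
    complement of the fragment 3' suffix; both truncate at the fragment end
    when the fragment is shorter than the read length.  The index read is the
    library barcode.  Every emitted base passes independently through the
    substitution channel.
    """
    if len(pool) == 0:
        raise ValueError("cannot sequence an empty fragment pool")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w = pool.weight / pool.weight.sum()
    chosen = rng.choice(len(pool), size=config.total_reads, p=w)

    rl = config.read_length
    r1, r2 = [], ([] if config.paired else None)
    origin, intact_flags = [], []
    for i in chosen:
        frag = pool.sequence(int(i))
        r1.append(frag[:rl])
        if config.paired:
            r2.append(revcomp(frag)[:rl])
        origin.append(pool.origins[pool.origin_idx[i]])
        intact_flags.append(bool(pool.intact[i]))

    idx_reads = [library_barcode.sequence] * config.total_reads
    p = config.per_base_error
    r1 = _mutate(r1, p, rng)
    if config.paired:
        r2 = _mutate(r2, p, rng)
    idx_reads = _mutate(idx_reads, p, rng)
    read_ids = [f"{id_prefix}:{k}" for k in range(config.total_reads)]
    return ReadBatch(read_ids, r1, r2, idx_reads, origin, np.array(intact_flags))


# ---------------------------------------------------------------------------
# whole-experiment simulation


def _sample_pool(sample: SyntheticSample, sasi_copies: int) -> MoleculePool:
    """Material in one tube before any event: the genome plus spike-in
    fragments dosed by mass.  Each spike-in fragment is materialized
    ``sasi_copies`` times with down-scaled weights so that shearing and
    size-selection outcomes are ensemble-averaged rather than hinging on a
    single stochastic realization."""
    genome_mass = len(sample.genome)
    molecules: list[tuple[str, float, str]] = [(sample.genome, 1.0, f"genome:{sample.sample_id}")]
    for sset, frac in sample.sasi_sets:
        if frac == 0:
            continue
        # equimolar fragments: mass fraction -> molecule count per fragment
        copies_per_fragment = frac / (1 - frac) * genome_mass / sset.total_length
        w = copies_per_fragment / sasi_copies
        for frag in sset.fragments:
            label = f"sasi:bc{sset.barcode_id}:{frag.amplicon_name}"
            for _ in range(sasi_copies):
                molecules.append((frag.full_sequence, w, label))
    return MoleculePool.from_molecules(molecules)


@dataclass
class ExperimentResult:
    """Reads per demultiplexed tube plus the complete truth table."""

    batches: dict[str, ReadBatch]  # keyed by tube (library-barcode) sample id
    library_barcodes: dict[str, Barcode]  # tube sample id -> index barcode
    truth: pd.DataFrame  # read_id, tube_sample, material_sample, origin, event

    def write_fastq(self, outdir: str | Path, gzip: bool = False) -> dict[str, Path]:
        """Write multiplexed R1/R2/I1 FASTQ (phred+33, constant quality) and
        the truth table TSV.  Returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        suffix = ".fastq.gz" if gzip else ".fastq"
        paths = {
            "r1": outdir / f"R1{suffix}",
            "i1": outdir / f"I1{suffix}",
            "truth": outdir / "truth.tsv",
        }
        any_r2 = any(b.r2 is not None for b in self.batches.values())
        if any_r2:
            paths["r2"] = outdir / f"R2{suffix}"

        def opener(path: Path):
            return gzip_mod.open(path, "wt") if gzip else open(path, "w")

        with opener(paths["r1"]) as f1, opener(paths["i1"]) as fi:
            f2 = opener(paths["r2"]) if any_r2 else None
            try:
                for tube, batch in self.batches.items():
                    for k in range(len(batch)):
                        rid = batch.read_ids[k]
                        f1.write(f"@{rid}/1\n{batch.r1[k]}\n+\n{'I' * len(batch.r1[k])}\n")
                        fi.write(f"@{rid}\n{batch.index[k]}\n+\n{'I' * len(batch.index[k])}\n")
                        if f2 is not None and batch.r2 is not None:
                            f2.write(f"@{rid}/2\n{batch.r2[k]}\n+\n{'I' * len(batch.r2[k])}\n")
            finally:
                if f2 is not None:
                    f2.close()
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_experiment(
    samples: list[SyntheticSample],
    events: Sequence[ContaminationEvent | SwapEvent],
    shear: ShearModel,
    window: SizeSelection,
    config: ReadSimConfig,
    sasi_copies: int = 100,
) -> ExperimentResult:
    """Simulate a multiplexed spiked experiment with optional injected events.

    Contamination mixes source material (genome and its spike-ins) into the
    recipient tube at the stated relative fraction *before* shearing and
    library prep.  Swaps transpose two tubes after spiking, so spike-in tags
    follow the sample material while library barcodes follow the tube.
    Reads are split equally across tubes.  Fully deterministic for a fixed
    ``config.seed`` (per-stage seeds are spawned from it).
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    by_id = {s.sample_id: s for s in samples}
    for ev in events:
        refs = (
            (ev.recipient_sample, ev.source_sample)
            if isinstance(ev, ContaminationEvent)
            else (ev.sample_a, ev.sample_b)
        )
        for r in refs:
            if r not in by_id:
                raise ValueError(f"event references unknown sample {r!r}")

    # material per tube
    pools = {s.sample_id: _sample_pool(s, sasi_copies) for s in samples}
    for ev in events:
        if isinstance(ev, ContaminationEvent):
            src = _sample_pool(by_id[ev.source_sample], sasi_copies)
            contaminant = src.scaled(
                ev.relative_fraction, origin_prefix=f"contam[{ev.source_sample}]<-"
            )
            pools[ev.recipient_sample] = MoleculePool.concat(
                [pools[ev.recipient_sample], contaminant]
            )

    # swaps: permute the tube -> material mapping; barcodes stay with tubes
    material_of = {sid: sid for sid in ids}
    for ev in events:
        if isinstance(ev, SwapEvent):
            material_of[ev.sample_a], material_of[ev.sample_b] = (
                material_of[ev.sample_b],
                material_of[ev.sample_a],
            )

    n = len(samples)
    reads_per_tube = config.total_reads // n
    seeds = np.random.SeedSequence(config.seed).spawn(3 * n)

    batches: dict[str, ReadBatch] = {}
    lib_barcodes: dict[str, Barcode] = {}
    truth_rows = []
    for t, tube in enumerate(ids):
        material = material_of[tube]
        pool = pools[material]
        sheared = shear_molecules(
            pool,
            ShearModel(
                shear.target_mean_size,
                shear.dispersion,
                seed=seeds[3 * t].generate_state(1)[0] % (2**31),
            ),
        )
        selected = size_select(
            sheared,
            SizeSelection(
                window.lower,
                window.upper,
                window.edge_steepness,
                seed=seeds[3 * t + 1].generate_state(1)[0] % (2**31),
            ),
        )
        barcode = by_id[tube].library_barcode
        lib_barcodes[tube] = barcode
        batch = simulate_reads(
            selected,
            ReadSimConfig(
                config.read_length,
                config.paired,
                config.per_base_error,
                reads_per_tube,
                seed=int(seeds[3 * t + 2].generate_state(1)[0] % (2**31)),
            ),
            barcode,
            id_prefix=tube,
        )
        batches[tube] = batch
        event_note = "swap" if material != tube else ""
        for k in range(len(batch)):
            origin = batch.origin[k]
            note = event_note
            if origin.startswith("contam["):
                note = (note + "+contamination").lstrip("+")
            truth_rows.append((batch.read_ids[k], tube, material, origin, note))

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "tube_sample", "material_sample", "origin", "event"]
    )
    return ExperimentResult(batches, lib_barcodes, truth)


# ---------------------------------------------------------------------------
# count-level mode


def count_level_simulate(
    plex: int,
    reads_per_sample: int,
    dose: float,
    events: Sequence[ContaminationEvent] = (),
    replicates: int = 1,
    seed: int = 1,
) -> pd.DataFrame:
    """Binomial surrogate for spike-in read counts.

    Samples are labelled S1..Sn, each carrying spike-in barcode id equal to
    its index.  Own-barcode counts ~ Binomial(reads_per_sample, dose);
    a contamination event adds foreign counts ~ Binomial(reads_per_sample,
    dose * relative_fraction) for the source's barcode in the recipient row.
    Returns a tidy table (replicate, sample, sasi_barcode, count).
    """
    if plex < 1 or reads_per_sample < 1 or replicates < 1:
        raise ValueError("plex, reads_per_sample and replicates must be positive")
    if not (0.0 <= dose <= 1.0):
        raise ValueError("dose must lie in [0,1]")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1}" for i in range(plex)]
    own_id = {sid: i + 1 for i, sid in enumerate(sample_ids)}
    rows = []
    for rep in range(1, replicates + 1):
        own = rng.binomial(reads_per_sample, dose, size=plex)
        for i, sid in enumerate(sample_ids):
            rows.append((rep, sid, own_id[sid], int(own[i])))
        for ev in events:
            if ev.recipient_sample not in own_id or ev.source_sample not in own_id:
                raise ValueError("event references unknown sample")
            c = int(rng.binomial(reads_per_sample, dose * ev.relative_fraction))
            rows.append((rep, ev.recipient_sample, own_id[ev.source_sample], c))
    df = pd.DataFrame(rows, columns=["replicate", "sample", "sasi_barcode", "count"])
    return df.groupby(["replicate", "sample", "sasi_barcode"], as_index=False)["count"].sum()
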