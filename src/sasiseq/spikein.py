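"""Construction of barcoded spike-in fragments by in-silico PCR.

Spike-in fragments are amplicons of a reference that is never expected in
real samples (classically the PhiX174 control genome), produced from three
forward primers sharing one reverse primer so the three products span the
insert-size range of a typical short-read library (~200/400/600 bp).  A
sample barcode placed at the 5' end of the forward primer (and optionally,
reverse-complemented, at the reverse primer) travels with the fragment
through library preparation, letting the sequence data report which sample
the material came from.
"""

from __future__ import annotations

from dataclasses import dataclass

from .barcodes import Barcode

__all__ = [
    "PrimerPair",
    "AmpliconTemplate",
    "SASIFragment",
    "SASISet",
    "DosePlan",
    "PHIX_PRIMERS",
    "NEXTERA_FORWARD_FLANK",
    "NEXTERA_REVERSE_FLANK",
    "revcomp",
    "build_amplicon",
    "make_sasi_set",
    "spike_in_scaling",
    "expected_sasi_reads",
    "sasi_set_to_fasta_records",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_acgt(seq: str, what: str) -> None:
    if not seq or any(c not in "ACGT" for c in seq):
        raise ValueError(f"{what} must be non-empty and ACGT-only")


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primer cores, both given as synthesized.

    The reverse core anneals to the top strand, i.e. its reverse complement
    appears on the reference top strand downstream of the forward site.
    """

    forward_core: str
    reverse_core: str
    name: str = ""

    def __post_init__(self) -> None:
        _check_acgt(self.forward_core, "forward primer core")
        _check_acgt(self.reverse_core, "reverse primer core")


#: Primer cores for the three PhiX-derived amplicons (A/B/C share one reverse
#: primer); against the PhiX reference they produce 214, 397 and 568 bp
#: products respectively.
PHIX_PRIMERS = {
    "A": PrimerPair("GGCGCTCGTCTTTGGTATGTA", "GGCGTCCATCTCGAAG", "A"),
    "B": PrimerPair("TGAATTGTTCGCGTTTACCTT", "GGCGTCCATCTCGAAG", "B"),
    "C": PrimerPair("GTACGCTGGACTTTGTAGGAT", "GGCGTCCATCTCGAAG", "C"),
}

#: Fixed transposase-added adapter sequences; prepended/appended so fragments
#: amplify in Nextera-style PCR workflows.
NEXTERA_FORWARD_FLANK = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
NEXTERA_REVERSE_FLANK = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"


@dataclass(frozen=True)
class AmpliconTemplate:
    """An amplicon extracted from a reference, 1-based inclusive coordinates."""

    name: str
    sequence: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"amplicon {self.name}: span {self.start}..{self.end} does not "
                f"match sequence length {len(self.sequence)}"
            )


class PrimerSiteError(ValueError):
    """A primer site is missing, duplicated, or mis-oriented on the reference."""


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def build_amplicon(reference: str, primers: PrimerPair, name: str | None = None) -> AmpliconTemplate:
    """In-silico PCR: locate the exact forward site and the exact reverse
    binding site (reverse complement of the reverse core) downstream of it,
    and return the inclusive product.

    Matching is exact; primers are assumed to match the reference perfectly.
    Coordinates are 1-based inclusive on the top strand.
    """
    reference = reference.upper()
    _check_acgt(reference, "reference")
    fwd_hits = _find_all(reference, primers.forward_core)
    if not fwd_hits:
        raise PrimerSiteError(f"forward primer {primers.forward_core} not found in reference")
    if len(fwd_hits) > 1:
        raise PrimerSiteError(
            f"forward primer {primers.forward_core} matches at multiple positions: "
            f"{[h + 1 for h in fwd_hits]}"
        )
    rev_site = revcomp(primers.reverse_core)
    rev_hits = _find_all(reference, rev_site)
    if not rev_hits:
        raise PrimerSiteError(f"reverse primer site {rev_site} not found in reference")
    if len(rev_hits) > 1:
        raise PrimerSiteError(
            f"reverse primer site {rev_site} matches at multiple positions: "
            f"{[h + 1 for h in rev_hits]}"
        )
    f0 = fwd_hits[0]
    r0 = rev_hits[0]
    if r0 < f0 + len(primers.forward_core):
        raise PrimerSiteError(
            f"reverse primer site (pos {r0 + 1}) lies upstream of the forward site "
            f"(pos {f0 + 1}); no product on this strand"
        )
    end = r0 + len(rev_site)  # exclusive, 0-based
    return AmpliconTemplate(
        name=name if name is not None else primers.name,
        sequence=reference[f0:end],
        start=f0 + 1,
        end=end,
    )


@dataclass(frozen=True)
class SASIFragment:
    """A barcode-tagged amplicon ready for spiking."""

    barcode_id: int
    amplicon_name: str
    tagging_mode: str  # forward_only | both_ends
    nextera_flanks: bool
    full_sequence: str

    @property
    def length(self) -> int:
        return len(self.full_sequence)


@dataclass(frozen=True)
class SASISet:
    """The three same-barcode fragments mixed equimolar (1:1:1 molecules)."""

    barcode_id: int
    fragments: tuple[SASIFragment, SASIFragment, SASIFragment]
    tagging_mode: str

    @property
    def total_length(self) -> int:
        return sum(f.length for f in self.fragments)


def make_sasi_set(
    amplicons: dict[str, AmpliconTemplate] | list[AmpliconTemplate],
    barcode: Barcode,
    tagging_mode: str = "forward_only",
    nextera_flanks: bool = False,
) -> SASISet:
    """Tag three amplicons with one barcode.

    ``forward_only`` prepends the barcode to the amplicon 5' end (the mode of
    a typical multiplexed experiment); ``both_ends`` additionally appends the
    reverse complement of the barcode at the 3' terminus.  Nextera flanks, if
    requested, wrap the tagged fragment with the fixed transposase adapter
    sequences (33 bp at the 5' end, 34 bp reverse-complemented at the 3'
    end).
    """
    if tagging_mode not in ("forward_only", "both_ends"):
        raise ValueError(f"unknown tagging_mode {tagging_mode!r}")
    amps = list(amplicons.values()) if isinstance(amplicons, dict) else list(amplicons)
    if len(amps) != 3 or len({a.name for a in amps}) != 3:
        raise ValueError("a spike-in set needs exactly three distinctly named amplicons")
    _check_acgt(barcode.sequence, "barcode")
    frags = []
    for amp in amps:
        seq = barcode.sequence + amp.sequence
        if tagging_mode == "both_ends":
            seq = seq + revcomp(barcode.sequence)
        if nextera_flanks:
            seq = NEXTERA_FORWARD_FLANK + seq + revcomp(NEXTERA_REVERSE_FLANK)
        frags.append(
            SASIFragment(barcode.id, amp.name, tagging_mode, nextera_flanks, seq)
        )
    return SASISet(barcode.id, tuple(frags), tagging_mode)


@dataclass(frozen=True)
class DosePlan:
    """Spike-in dosing: mass fraction relative to sample DNA, plex, lane yield."""

    mass_fraction: float = 0.001
    plex: int = 96
    reads_per_lane: int = 96_000_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.mass_fraction <= 1.0):
            raise ValueError("mass_fraction must lie in [0,1]")
        if self.plex < 1:
            raise ValueError("plex must be >= 1")


def spike_in_scaling(baseline_fraction: float, baseline_plex: int, new_plex: int) -> float:
    """Rescale the spike-in mass fraction to keep the expected spike-in read
    count per sample constant at fixed lane yield: fraction scales linearly
    with plex (0.1% at 96-plex becomes 0.4% at 384-plex)."""
    if baseline_plex <= 0 or new_plex <= 0:
        raise ValueError("plex values must be positive")
    if baseline_fraction < 0:
        raise ValueError("baseline_fraction must be non-negative")
    return baseline_fraction * new_plex / baseline_plex


def expected_sasi_reads(dose: DosePlan) -> float:
    """Expected spike-in reads per sample: lane yield is split across the
    plex and the spike occupies its mass fraction of each sample's reads."""
    if dose.reads_per_lane <= 0:
        raise ValueError("reads_per_lane must be positive")
    return dose.reads_per_lane / dose.plex * dose.mass_fraction


def sasi_set_to_fasta_records(sset: SASISet) -> list[tuple[str, str]]:
    """(header, sequence) pairs; headers encode barcode id, amplicon, mode."""
    recs = []
    for frag in sset.fragments:
        flanks = "+nextera" if frag.nextera_flanks else ""
        header = f"sasi_bc{frag.barcode_id}_{frag.amplicon_name}_{frag.tagging_mode}{flanks}"
        recs.append((header, frag.full_sequence))
    return recs


def parse_sasi_records(records: list[tuple[str, str]]) -> list[SASISet]:
    """Rebuild spike-in sets from FASTA records written by
    :func:`sasi_set_to_fasta_records` (round-trip identity on sequences)."""
    frags: dict[int, list[SASIFragment]] = {}
    modes: dict[int, str] = {}
    for header, seq in records:
        parts = header.split("_")
        if len(parts) < 4 or not parts[1].startswith("bc"):
            raise ValueError(f"unrecognized spike-in FASTA header {header!r}")
        bc_id = int(parts[1][2:])
        amp_name = parts[2]
        mode_token = parts[3]
        nextera = mode_token.endswith("+nextera")
        mode = mode_token.removesuffix("+nextera")
        if len(parts) > 4:  # tagging mode itself contains an underscore
            mode_token2 = parts[4]
            nextera = mode_token2.endswith("+nextera")
            mode = f"{mode}_{mode_token2.removesuffix('+nextera')}"
        frags.setdefault(bc_id, []).append(
            SASIFragment(bc_id, amp_name, mode, nextera, seq)
        )
        modes[bc_id] = mode
    sets = []
    for bc_id in sorted(frags):
        fl = sorted(frags[bc_id], key=lambda f: f.amplicon_name)
        if len(fl) != 3:
            raise ValueError(f"barcode {bc_id}: expected 3 fragments, found {len(fl)}")
        sets.append(SASISet(bc_id, tuple(fl), modes[bc_id]))
    return sets


def synthetic_primer_site_reference(seed: int = 6, length: int = 1500) -> str:
    """SYNTHETIC stand-in reference for the worked example.

    A random background with the canonical primer cores embedded at spacings
    that yield the documented 214/397/568 bp products (the nested three-
    amplicon layout, common reverse site).  It is *not* the PhiX genome —
    reproducing the published coordinates requires downloading accession
    NC_001422.1 and running :func:`build_amplicon` against it.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    c0 = 100  # forward C start; A/B starts follow from the product sizes
    layout = {
        "C": (c0, PHIX_PRIMERS["C"].forward_core),
        "B": (c0 + 568 - 397, PHIX_PRIMERS["B"].forward_core),
        "A": (c0 + 568 - 214, PHIX_PRIMERS["A"].forward_core),
    }
    for pos, core in layout.values():
        seq[pos : pos + len(core)] = list(core)
    rev_site = revcomp(PHIX_PRIMERS["A"].reverse_core)
    end = c0 + 568
    seq[end - len(rev_site) : end] = list(rev_site)
    ref = "".join(seq)
    for primers in PHIX_PRIMERS.values():
        build_amplicon(ref, primers)  # raises if the background collides
    return ref


def extract_amplicon_bodies(
    sets: list[SASISet], barcode_length: int
) -> dict[str, AmpliconTemplate]:
    """Recover the untagged amplicon bodies from tagged fragments by
    stripping the barcode (and any Nextera flanks) at the known offsets."""
    bodies: dict[str, AmpliconTemplate] = {}
    for sset in sets:
        for frag in sset.fragments:
            seq = frag.full_sequence
            if frag.nextera_flanks:
                seq = seq[len(NEXTERA_FORWARD_FLANK) : len(seq) - len(NEXTERA_REVERSE_FLANK)]
            seq = seq[barcode_length:]
            if frag.tagging_mode == "both_ends":
                seq = seq[: len(seq) - barcode_length]
            prev = bodies.get(frag.amplicon_name)
            if prev is None:
                bodies[frag.amplicon_name] = AmpliconTemplate(
                    frag.amplicon_name, seq, 1, len(seq)
                )
            elif prev.sequence != seq:
                raise ValueError(
                    f"amplicon {frag.amplicon_name}: inconsistent bodies across barcodes"
                )
    return bodies
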