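"""Synthetic diploid genomes, contact models and 4C read sets with ground truth.

The generator emulates the statistical structure an allele-specific 4C-seq
analysis relies on: an F1-hybrid diploid genome whose haplotypes share the
first-cutter fragment grid but differ at SNPs (including one that creates a
second-cutter RFLP on one allele), a polymer-physics contact model with
power-law cis decay, a multi-megabase topological domain with sharply
attenuated cross-boundary contacts, preferred far-cis/trans contact regions,
an optional one-allele deletion that brings the two locus ends linearly
close, and a transcribed-interval track with distinct activity levels in
"active" versus "inactive" compartments.

All generators take explicit seeds and are deterministic; nucleotide
composition is uniform, so first-cutter spacing is analytically ~4**6 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .fragmentome import (
    FragmentEndDB,
    FragmentMap,
    RFLPSite,
    build_fragment_end_db,
    find_sites,
    resolve_enzyme,
    revcomp,
)
from .alleleseq import ViewpointSpec

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class Snp(NamedTuple):
    chrom: str
    pos: int
    base_a: str
    base_b: str


@dataclass
class GenomeSpec:
    """What to generate: chromosome sizes and SNP counts."""

    chromosomes: dict[str, int]
    n_snps: int = 20
    plant_rflp: bool = True
    forced_snps: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        for chrom, length in self.chromosomes.items():
            if length < 10_000:
                raise ValueError(f"chromosome {chrom} shorter than 10 kb")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")


@dataclass
class HaplotypePair:
    """Two same-length haplotype sequences differing exactly at the listed SNPs."""

    chrom_names: list[str]
    seq_a: dict[str, str]
    seq_b: dict[str, str]
    snps: list[Snp]
    #: per-allele SNP coordinates; diverge only after a deletion
    snp_positions: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.snp_positions:
            self.snp_positions = {
                "A": [s.pos for s in self.snps],
                "B": [s.pos for s in self.snps],
            }

    def seq(self, allele: str) -> dict[str, str]:
        return {"A": self.seq_a, "B": self.seq_b}[allele]

    def lengths(self, allele: str = "A") -> dict[str, int]:
        return {c: len(s) for c, s in self.seq(allele).items()}

    def to_fasta(self, path: str | Path, allele: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.chrom_names:
                fh.write(f">{chrom}\n")
                seq = self.seq(allele)[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.snps],
                "pos_a": self.snp_positions["A"],
                "pos_b": self.snp_positions["B"],
                "base_a": [s.base_a for s in self.snps],
                "base_b": [s.base_b for s in self.snps],
            }
        )


def _no_site_overlap(arr: np.ndarray, lo_edit: int, hi_edit: int, site: str) -> bool:
    """True iff no occurrence of ``site`` overlaps ``[lo_edit, hi_edit)`` in ``arr``."""
    k = len(site)
    lo = max(0, lo_edit - k + 1)
    hi = min(len(arr), hi_edit + k - 1)
    win = arr[lo:hi].tobytes().decode()
    for p in find_sites(win, site):
        if lo + p < hi_edit and lo + p + k > lo_edit:
            return False
    return True


def _edit_region(
    arrs: Sequence[np.ndarray],
    lo: int,
    hi: int,
    replacements: Sequence[bytes],
    guard_sites: Sequence[str],
) -> None:
    """Apply per-haplotype replacements over ``[lo, hi)`` if no guarded site
    overlaps the region before or after the edit; raise and roll back otherwise."""
    for arr in arrs:
        for site in guard_sites:
            if not _no_site_overlap(arr, lo, hi, site):
                raise ValueError(
                    f"edit at [{lo},{hi}) would destroy a {site} recognition site"
                )
    backups = [arr[lo:hi].copy() for arr in arrs]
    for arr, rep in zip(arrs, replacements):
        arr[lo:hi] = np.frombuffer(rep, dtype=np.uint8)
    for arr in arrs:
        for site in guard_sites:
            if not _no_site_overlap(arr, lo, hi, site):
                for a, bak in zip(arrs, backups):
                    a[lo:hi] = bak
                raise ValueError(
                    f"edit at [{lo},{hi}) would create a {site} recognition site"
                )


def plant_snp(
    seq_a: np.ndarray,
    seq_b: np.ndarray,
    pos: int,
    base_a: Optional[str] = None,
    base_b: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
    first_site: str = "AAGCTT",
    protect_second: Optional[str] = None,
) -> tuple[str, str]:
    """Place one SNP at ``pos`` on mutable uint8 haplotype arrays.

    The reference base becomes allele A's base unless overridden; allele B
    gets a different base.  Raises (leaving the arrays untouched) if the
    edit would create or destroy a ``first_site`` occurrence on either
    haplotype — that would break the shared fragment grid — or a
    ``protect_second`` site when one is given.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    ref = chr(seq_a[pos])
    ba = base_a if base_a is not None else ref
    if base_b is None:
        others = [b for b in "ACGT" if b != ba]
        bb = others[int(rng.integers(len(others)))]
    else:
        bb = base_b
    if ba == bb:
        raise ValueError("SNP alleles must differ")
    guards = [first_site] + ([protect_second] if protect_second else [])
    _edit_region(
        [seq_a, seq_b], pos, pos + 1, [ba.encode(), bb.encode()], guards
    )
    return ba, bb


def _plant_rflp_context(
    seq_a: np.ndarray, seq_b: np.ndarray, pos: int, first_site: str = "AAGCTT"
) -> tuple[str, str]:
    """Write a shared GAT context at [pos-3, pos) and an A/C SNP at ``pos``,
    so allele B (and only B) carries a GATC second-cutter site there."""
    backup_a = seq_a[pos - 3 : pos + 1].copy()
    backup_b = seq_b[pos - 3 : pos + 1].copy()
    _edit_region(
        [seq_a, seq_b], pos - 3, pos + 1, [b"GATA", b"GATC"], [first_site]
    )
    lo = max(0, pos - 6)
    if b"GATC" in seq_a[lo : pos + 4].tobytes():
        # allele A accidentally carries a site in the same window: the RFLP
        # would not be allele-exclusive
        seq_a[pos - 3 : pos + 1] = backup_a
        seq_b[pos - 3 : pos + 1] = backup_b
        raise ValueError("window not allele-exclusive for the second cutter")
    return "A", "C"


def generate_haplotypes(spec: GenomeSpec, seed: int) -> HaplotypePair:
    """Generate an F1-like haplotype pair with planted SNPs.

    Haplotypes are identical except at SNP positions.  SNPs never touch a
    first-cutter recognition site on either haplotype, so both alleles share
    one fragment grid.  When ``plant_rflp`` is set, the first chromosome
    receives a SNP whose B allele completes a GATC (second-cutter) site,
    exercising the RFLP-based single-end strategy.  Explicitly forced SNP
    positions that would disrupt the grid raise ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    seq_a: dict[str, np.ndarray] = {}
    for chrom, length in spec.chromosomes.items():
        seq_a[chrom] = _BASES[rng.integers(0, 4, size=length)].copy()
    seq_b = {c: a.copy() for c, a in seq_a.items()}

    snps: list[Snp] = []
    taken: dict[str, list[int]] = {c: [] for c in spec.chromosomes}

    def far_enough(chrom: str, pos: int, min_gap: int = 12) -> bool:
        return all(abs(pos - p) >= min_gap for p in taken[chrom])

    if spec.plant_rflp:
        chrom = next(iter(spec.chromosomes))
        for _attempt in range(1000):
            pos = int(rng.integers(50, spec.chromosomes[chrom] - 50))
            try:
                ba, bb = _plant_rflp_context(seq_a[chrom], seq_b[chrom], pos)
            except ValueError:
                continue
            snps.append(Snp(chrom, pos, ba, bb))
            taken[chrom].append(pos)
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("failed to plant RFLP SNP")

    for chrom, pos in spec.forced_snps:
        ba, bb = plant_snp(seq_a[chrom], seq_b[chrom], pos, rng=rng)
        snps.append(Snp(chrom, pos, ba, bb))
        taken[chrom].append(pos)

    chrom_names = list(spec.chromosomes)
    weights = np.array([spec.chromosomes[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    planted = 0
    attempts = 0
    while planted < spec.n_snps:
        attempts += 1
        if attempts > 100 * max(spec.n_snps, 1):  # pragma: no cover
            raise RuntimeError("failed to plant requested SNPs")
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
        pos = int(rng.integers(10, spec.chromosomes[chrom] - 10))
        if not far_enough(chrom, pos):
            continue
        try:
            ba, bb = plant_snp(seq_a[chrom], seq_b[chrom], pos, rng=rng)
        except ValueError:
            continue
        snps.append(Snp(chrom, pos, ba, bb))
        taken[chrom].append(pos)
        planted += 1

    order = {c: i for i, c in enumerate(chrom_names)}
    snps.sort(key=lambda s: (order[s.chrom], s.pos))
    return HaplotypePair(
        chrom_names=chrom_names,
        seq_a={c: a.tobytes().decode() for c, a in seq_a.items()},
        seq_b={c: a.tobytes().decode() for c, a in seq_b.items()},
        snps=snps,
    )


@dataclass
class Liftover:
    """Coordinate map for a single deletion: old position -> new position."""

    chrom: str
    start: int
    end: int

    @property
    def shift(self) -> int:
        return self.end - self.start

    def lift(self, pos: int) -> Optional[int]:
        if pos < self.start:
            return pos
        if pos < self.end:
            return None
        return pos - self.shift


def apply_deletion(
    hap: HaplotypePair,
    which_allele: str,
    chrom: str,
    start: int,
    end: int,
    viewpoint: Optional[tuple[str, int]] = None,
) -> tuple[HaplotypePair, Liftover]:
    """Remove ``[start, end)`` from one allele's chromosome.

    Models a V(D)J-like deletion: the chosen allele's sequence shortens by
    the interval length, SNPs inside the interval are dropped, downstream
    SNP coordinates on that allele shift by -(end-start), and the returned
    :class:`Liftover` maps old to new coordinates.  A deletion overlapping
    the viewpoint (when given) is an error.
    """
    if which_allele not in ("A", "B"):
        raise ValueError("allele must be 'A' or 'B'")
    seqs = dict(hap.seq(which_allele))
    if not (0 <= start <= end <= len(seqs[chrom])):
        raise ValueError("deletion interval outside chromosome bounds")
    if viewpoint is not None and viewpoint[0] == chrom:
        if start <= viewpoint[1] < end:
            raise ValueError("deletion interval overlaps the viewpoint")
    lift = Liftover(chrom, start, end)
    seqs[chrom] = seqs[chrom][:start] + seqs[chrom][end:]

    keep_snps: list[Snp] = []
    pos_a: list[int] = []
    pos_b: list[int] = []
    for snp, pa, pb in zip(hap.snps, hap.snp_positions["A"], hap.snp_positions["B"]):
        own = pa if which_allele == "A" else pb
        if snp.chrom == chrom and own is not None and start <= own < end:
            continue  # dropped from that allele's coordinate map
        if snp.chrom == chrom:
            if which_allele == "A":
                pa = lift.lift(pa)
            else:
                pb = lift.lift(pb)
        keep_snps.append(snp)
        pos_a.append(pa)
        pos_b.append(pb)

    new = HaplotypePair(
        chrom_names=list(hap.chrom_names),
        seq_a=seqs if which_allele == "A" else dict(hap.seq_a),
        seq_b=seqs if which_allele == "B" else dict(hap.seq_b),
        snps=keep_snps,
        snp_positions={"A": pos_a, "B": pos_b},
    )
    return new, lift


# -- contact model ---------------------------------------------------------

@dataclass
class DomainInterval:
    chrom: str
    start: int
    end: int
    attenuation: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.attenuation < 1:
            raise ValueError("boundary attenuation must be in (0, 1)")


@dataclass
class EnrichedRegion:
    chrom: str
    start: int
    end: int
    fold: float = 8.0

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold enrichment must be >= 1")


@dataclass
class ContactModel:
    """Ground-truth contact distribution for one viewpoint on one allele.

    Cis contact probability decays as distance**-decay_exponent, attenuated
    once per topological-domain boundary crossed and multiplied by the fold
    factor inside enriched regions.  Trans fragment ends share ``trans_rate``
    of the total mass, uniformly before enrichment.
    """

    viewpoint: tuple[str, int]
    decay_exponent: float = 1.0
    domain_intervals: list[DomainInterval] = field(default_factory=list)
    enriched_regions: list[EnrichedRegion] = field(default_factory=list)
    trans_rate: float = 0.0
    deletion: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be > 0")
        if not 0 <= self.trans_rate < 1:
            raise ValueError("trans_rate must be in [0, 1)")
        if self.deletion is not None:
            chrom, s, e = self.deletion
            if chrom == self.viewpoint[0] and s <= self.viewpoint[1] < e:
                raise ValueError("deletion interval contains the viewpoint")


def contact_probabilities(model: ContactModel, db: FragmentEndDB) -> np.ndarray:
    """Per-fragment-end contact probabilities under ``model`` over ``db``.

    The viewpoint's own fragment and its two immediate neighbours get
    probability zero (self-ligation and undigested product territory).  The
    vector sums to one.
    """
    if len(db) == 0:
        raise ValueError("empty fragment-end database")
    vp_chrom, vp_pos = model.viewpoint
    vp_frag = db.fragment_map.frag_id_at(vp_chrom, vp_pos)
    ends = db.ends
    chroms = ends["chrom"].to_numpy()
    mid = db.midpoints
    frag_ids = ends["frag_id"].to_numpy()

    excluded = np.isin(frag_ids, [vp_frag - 1, vp_frag, vp_frag + 1]) & (
        chroms == vp_chrom
    )
    cis = (chroms == vp_chrom) & ~excluded
    trans = chroms != vp_chrom

    w = np.zeros(len(ends), dtype=float)
    d = np.abs(mid[cis] - vp_pos)
    d = np.maximum(d, 1.0)
    w[cis] = d ** (-model.decay_exponent)

    # one attenuation factor per domain boundary between the end and the viewpoint
    for dom in model.domain_intervals:
        if dom.chrom != vp_chrom:
            continue
        for bound in (dom.start, dom.end):
            crossed = cis & (
                (np.minimum(mid, vp_pos) < bound) & (bound <= np.maximum(mid, vp_pos))
            )
            w[crossed] *= dom.attenuation

    w[trans] = 1.0
    for reg in model.enriched_regions:
        inside = (chroms == reg.chrom) & (mid >= reg.start) & (mid < reg.end)
        w[inside & ~excluded] *= reg.fold

    p = np.zeros_like(w)
    cis_sum = w[cis].sum()
    trans_sum = w[trans].sum()
    if trans_sum == 0 and model.trans_rate > 0:
        raise ValueError("trans_rate > 0 but the database has no trans ends")
    cis_mass = 1.0 - model.trans_rate if trans_sum > 0 else 1.0
    if cis_sum > 0:
        p[cis] = cis_mass * w[cis] / cis_sum
    if trans_sum > 0:
        p[trans] = model.trans_rate * w[trans] / trans_sum
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):  # pragma: no cover - defensive
        p /= total
    return p


# -- read simulation -------------------------------------------------------

@dataclass
class ReadSimSpec:
    n_reads: int
    read_len: int = 36
    strategy: str = "PE"
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.strategy not in ("PE", "SE"):
            raise ValueError("strategy must be 'PE' or 'SE'")


@dataclass
class SimulatedReads:
    """FASTQ-ready reads plus the per-read ground truth."""

    ids: list[str]
    read1: list[str]
    read2: Optional[list[str]]
    truth: pd.DataFrame  # read_id, allele, chrom, frag_end_id, truncated

    def pairs(self) -> list[tuple[str, str, str]]:
        if self.read2 is None:
            raise ValueError("single-end simulation has no read 2")
        return list(zip(self.ids, self.read1, self.read2))

    def single(self) -> list[tuple[str, str]]:
        return list(zip(self.ids, self.read1))

    def write_fastq(self, directory: str | Path, prefix: str) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out: list[Path] = []
        if self.read2 is None:
            files = [(directory / f"{prefix}.fastq", self.read1)]
        else:
            files = [
                (directory / f"{prefix}_R1.fastq", self.read1),
                (directory / f"{prefix}_R2.fastq", self.read2),
            ]
        for path, reads in files:
            with open(path, "w") as fh:
                for rid, seq in zip(self.ids, reads):
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            out.append(path)
        return out

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if len(hits) == 0:
        return seq
    lut = {ord(b): [ord(c) for c in "ACGT" if c != b] for b in "ACGT"}
    for i in hits:
        arr[i] = lut[arr[i]][int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_reads(
    hap: HaplotypePair,
    models: Mapping[str, ContactModel],
    dbs: Mapping[str, FragmentEndDB],
    sim: ReadSimSpec,
    vp: ViewpointSpec,
) -> SimulatedReads:
    """Sample 4C reads from per-allele contact models.

    Each read draws its allele 50/50 (F1 diploid), then a fragment end from
    that allele's contact-probability vector.  Read 1 is the allele's
    viewpoint P1 sequence followed by the captured end's oriented sequence;
    for the PE strategy read 2 is the viewpoint-local P2 sequence whose SNP
    base identifies the allele.  Substitution errors are applied at
    ``sim.error_rate``.  Ends shorter than the capture length are emitted
    truncated and flagged in the truth table.
    """
    rng = np.random.default_rng(sim.seed)
    p1_seq = {
        al: hap.seq(al)[vp.chrom][vp.p1_start : vp.p1_end] for al in ("A", "B")
    }
    if sim.read_len < len(vp.p1_seq) + 4:
        raise ValueError("read_len must be >= primer length + 4")
    cap_len = sim.read_len - len(vp.p1_seq)
    p2_seq = None
    if vp.strategy == "PE":
        p2_seq = {
            al: hap.seq(al)[vp.chrom][vp.p2_start : vp.p2_end] for al in ("A", "B")
        }

    probs = {al: contact_probabilities(models[al], dbs[al]) for al in ("A", "B")}
    oriented = {
        al: [dbs[al].oriented_sequence(i) for i in range(len(dbs[al]))]
        for al in ("A", "B")
    }

    alleles = np.where(rng.random(sim.n_reads) < 0.5, "A", "B")
    end_choice = np.empty(sim.n_reads, dtype=np.int64)
    for al in ("A", "B"):
        mask = alleles == al
        n = int(mask.sum())
        if n:
            end_choice[mask] = rng.choice(len(probs[al]), size=n, p=probs[al])

    ids: list[str] = []
    r1: list[str] = []
    r2: list[str] | None = [] if vp.strategy == "PE" else None
    rows = []
    for i in range(sim.n_reads):
        al = str(alleles[i])
        eid = int(end_choice[i])
        capture = oriented[al][eid][:cap_len]
        truncated = len(capture) < cap_len
        seq1 = _apply_errors(p1_seq[al] + capture, rng, sim.error_rate)
        rid = f"read{i:07d}"
        ids.append(rid)
        r1.append(seq1)
        if r2 is not None:
            r2.append(_apply_errors(p2_seq[al], rng, sim.error_rate))
        chrom = dbs[al].ends["chrom"].iat[eid]
        rows.append((rid, al, chrom, eid, truncated, len(capture)))

    truth = pd.DataFrame(
        rows,
        columns=["read_id", "allele", "chrom", "frag_end_id", "truncated", "capture_len"],
    )
    return SimulatedReads(ids=ids, read1=r1, read2=r2, truth=truth)


# -- expression track ------------------------------------------------------

def merge_intervals(
    intervals: Sequence[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping/adjacent (chrom, start, end) intervals."""
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


def simulate_expression_track(
    active_intervals: Sequence[tuple[str, int, int]],
    chrom_lengths: Mapping[str, int],
    active_fraction_active: float,
    active_fraction_inactive: float,
    seed: int,
    block: int = 1000,
) -> list[tuple[str, int, int]]:
    """Transcribed-interval BED track with compartment-specific activity.

    ``active_intervals`` designate the "active" compartment; inside them a
    fraction ``active_fraction_active`` of bases is transcribed, elsewhere
    ``active_fraction_inactive``.  Transcription is laid down in ``block``-bp
    units chosen without replacement, so realized fractions match the target
    up to one block per region.  Output intervals are sorted, non-overlapping.
    """
    for frac in (active_fraction_active, active_fraction_inactive):
        if not 0 <= frac <= 1:
            raise ValueError("transcribed fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    active = merge_intervals(active_intervals)
    regions: list[tuple[str, int, int, float]] = [
        (c, s, e, active_fraction_active) for c, s, e in active
    ]
    for chrom, length in chrom_lengths.items():
        cursor = 0
        for c, s, e in active:
            if c != chrom:
                continue
            if s > cursor:
                regions.append((chrom, cursor, s, active_fraction_inactive))
            cursor = max(cursor, e)
        if cursor < length:
            regions.append((chrom, cursor, length, active_fraction_inactive))

    transcribed: list[tuple[str, int, int]] = []
    for chrom, s, e, frac in regions:
        if frac == 0 or e <= s:
            continue
        starts = np.arange(s, e, block)
        n_pick = int(round(frac * len(starts)))
        picked = rng.permutation(len(starts))[:n_pick]
        for i in np.sort(picked):
            transcribed.append((chrom, int(starts[i]), int(min(starts[i] + block, e))))
    return merge_intervals(transcribed)


def write_bed(intervals: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


# -- viewpoint design ------------------------------------------------------

def _viewpoint_fragments(fmap: FragmentMap, chrom: str, pos: int, min_len: int):
    """Candidate fragments (start, end) near (chrom, pos), closest first.

    Only interior fragments qualify (both boundaries are cut sites) and they
    must be at least ``min_len`` long.
    """
    fid = fmap.frag_id_at(chrom, pos)
    frags = fmap.fragments[chrom]
    off = fmap._offsets[chrom]
    i0 = fid - off
    for delta in range(len(frags)):
        for i in sorted({i0 + delta, i0 - delta}):
            if 1 <= i < len(frags) - 1 and frags[i][1] - frags[i][0] >= min_len:
                yield frags[i]


def design_pe_viewpoint(
    hap: HaplotypePair,
    chrom: str,
    pos: int,
    name: str = "vp",
    primer_len: int = 20,
    read_len: int = 36,
    snp_offset: int = 10,
    seed: int = 0,
    first_cutter: str = "HindIII",
) -> tuple[HaplotypePair, ViewpointSpec]:
    """Place a PE viewpoint near (chrom, pos), planting its P2 SNP.

    The P1 primer occupies the last ``primer_len`` bases of the viewpoint
    fragment (reading across the downstream first-cutter junction); P2 is a
    ``read_len`` window deeper inside the fragment with a freshly planted
    SNP at ``snp_offset``.  Returns the edited haplotypes and the viewpoint.
    """
    _, site1, off1 = resolve_enzyme(first_cutter)
    fmap = FragmentMap.from_sequences(hap.seq_a, (site1, off1))
    min_len = primer_len + read_len + 20
    rng = np.random.default_rng(seed)
    a = np.frombuffer(hap.seq_a[chrom].encode(), dtype=np.uint8).copy()
    b = np.frombuffer(hap.seq_b[chrom].encode(), dtype=np.uint8).copy()

    placed = None
    for fs, fe in _viewpoint_fragments(fmap, chrom, pos, min_len):
        p1_start, p1_end = fe - primer_len, fe
        if not np.array_equal(a[p1_start:p1_end], b[p1_start:p1_end]):
            continue  # an existing SNP sits under the primer
        p2_start = fs + 8
        while p2_start + read_len <= p1_start - 4:
            snp_pos = p2_start + snp_offset
            try:
                ba, bb = plant_snp(a, b, snp_pos, rng=rng, protect_second="GATC")
            except ValueError:
                p2_start += 5
                continue
            placed = (fs, fe, p1_start, p1_end, p2_start, snp_pos, ba, bb)
            break
        if placed:
            break
    if placed is None:
        raise ValueError("no fragment suitable for a PE viewpoint near the request")
    fs, fe, p1_start, p1_end, p2_start, snp_pos, ba, bb = placed

    seq_a = dict(hap.seq_a)
    seq_b = dict(hap.seq_b)
    seq_a[chrom] = a.tobytes().decode()
    seq_b[chrom] = b.tobytes().decode()
    snps = hap.snps + [Snp(chrom, snp_pos, ba, bb)]
    order = {c: i for i, c in enumerate(hap.chrom_names)}
    snps.sort(key=lambda s: (order[s.chrom], s.pos))
    new_hap = HaplotypePair(
        chrom_names=list(hap.chrom_names), seq_a=seq_a, seq_b=seq_b, snps=snps
    )
    p1_seq = seq_a[chrom][p1_start:p1_end]
    vp = ViewpointSpec(
        name=name,
        chrom=chrom,
        pos=(fs + fe) // 2,
        strategy="PE",
        p1_start=p1_start,
        p1_end=p1_end,
        p1_seq=p1_seq,
        p2_start=p2_start,
        p2_end=p2_start + read_len,
        snp_offset=snp_offset,
        base_a=ba,
        base_b=bb,
    )
    return new_hap, vp


def design_se_viewpoint(
    hap: HaplotypePair,
    chrom: str,
    pos: int,
    name: str = "vp-se",
    primer_len: int = 24,
    seed: int = 0,
    first_cutter: str = "HindIII",
) -> tuple[HaplotypePair, ViewpointSpec]:
    """Place an SE viewpoint whose P1 region covers a planted RFLP SNP.

    A GATC-completing SNP is planted ``primer_len - 8`` bases inside the P1
    region on allele B, so allele-B molecules lose the primer-to-junction
    connection (their reads fail the exact viewpoint-sequence match) and the
    assay reads allele A only.
    """
    _, site1, off1 = resolve_enzyme(first_cutter)
    fmap = FragmentMap.from_sequences(hap.seq_a, (site1, off1))
    a = np.frombuffer(hap.seq_a[chrom].encode(), dtype=np.uint8).copy()
    b = np.frombuffer(hap.seq_b[chrom].encode(), dtype=np.uint8).copy()

    placed = None
    for fs, fe in _viewpoint_fragments(fmap, chrom, pos, primer_len + 30):
        p1_start, p1_end = fe - primer_len, fe
        snp_pos = p1_start + 8
        if not np.array_equal(
            a[p1_start:p1_end], b[p1_start:p1_end]
        ):
            continue  # an unrelated SNP sits under the primer
        try:
            ba, bb = _plant_rflp_context(a, b, snp_pos)
        except ValueError:
            continue
        placed = (fs, fe, p1_start, p1_end, snp_pos, ba, bb)
        break
    if placed is None:
        raise ValueError("no fragment suitable for an SE viewpoint near the request")
    fs, fe, p1_start, p1_end, snp_pos, ba, bb = placed

    seq_a = dict(hap.seq_a)
    seq_b = dict(hap.seq_b)
    seq_a[chrom] = a.tobytes().decode()
    seq_b[chrom] = b.tobytes().decode()
    snp = Snp(chrom, snp_pos, ba, bb)
    snps = hap.snps + [snp]
    order = {c: i for i, c in enumerate(hap.chrom_names)}
    snps.sort(key=lambda s: (order[s.chrom], s.pos))
    new_hap = HaplotypePair(
        chrom_names=list(hap.chrom_names), seq_a=seq_a, seq_b=seq_b, snps=snps
    )
    rflp = RFLPSite(chrom, snp_pos, ba, bb, gained_on="B", site_pos=snp_pos - 3)
    vp = ViewpointSpec(
        name=name,
        chrom=chrom,
        pos=(fs + fe) // 2,
        strategy="SE",
        p1_start=p1_start,
        p1_end=p1_end,
        p1_seq=seq_a[chrom][p1_start:p1_end],  # retained-allele sequence
        rflp=rflp,
        retained_allele="A",
    )
    return new_hap, vp


# -- canned scenarios (the study conditions) -------------------------------

@dataclass
class Scenario:
    """A fully wired synthetic study: genome, databases, models, viewpoints."""

    hap: HaplotypePair
    dbs: dict[str, FragmentEndDB]
    viewpoint: ViewpointSpec
    se_viewpoint: Optional[ViewpointSpec]
    models: dict[str, dict[str, ContactModel]]  # condition -> allele -> model
    expression: list[tuple[str, int, int]]
    active_regions: list[tuple[str, int, int]]
    seed: int


def default_scenario(
    seed: int = 1,
    n_snps: int = 30,
    cis_length: int = 10_000_000,
    trans_length: int = 6_000_000,
    read_len: int = 36,
    primer_len: int = 20,
) -> Scenario:
    """The compact study layout used for profile and boundary analyses.

    One 10 Mb cis chromosome carries the viewpoint at its centre inside a
    3 Mb topological domain with attenuation 0.1 at both boundaries, plus
    far-cis preferred-contact regions; one 6 Mb trans chromosome carries
    preferred trans regions.  Lymphoid alleles A and B share enriched
    regions while the "brain" condition contacts disjoint regions, and the
    expression track is active (40% transcribed) over the lymphoid regions
    versus 10% elsewhere.
    """
    chroms = {"chr12": cis_length, "chr2": trans_length}
    hap = generate_haplotypes(GenomeSpec(chroms, n_snps=n_snps), seed=seed)
    hap, vp = design_pe_viewpoint(
        hap, "chr12", cis_length // 2, name="3RR-like",
        primer_len=primer_len, read_len=read_len, seed=seed + 1,
    )
    hap, vp_se = design_se_viewpoint(
        hap, "chr12", int(cis_length * 0.69), name="UpIgH-like", seed=seed + 2
    )
    cap_len = read_len - primer_len
    dbs = {
        "A": build_fragment_end_db(hap.seq_a, map_prefix_len=cap_len),
        "B": build_fragment_end_db(hap.seq_b, map_prefix_len=cap_len),
    }
    vp.validate(dbs["A"].fragment_map)

    M = 1_000_000
    domain = DomainInterval("chr12", int(3.5 * M), int(6.5 * M), attenuation=0.1)
    lymphoid_regions = [
        ("chr12", int(0.8 * M), int(1.3 * M)),
        ("chr12", int(1.8 * M), int(2.3 * M)),
        ("chr12", int(7.4 * M), int(7.9 * M)),
        ("chr12", int(8.4 * M), int(8.9 * M)),
        ("chr2", int(0.8 * M), int(1.3 * M)),
        ("chr2", int(2.6 * M), int(3.1 * M)),
        ("chr2", int(4.4 * M), int(4.9 * M)),
    ]
    brain_regions = [
        ("chr12", int(0.2 * M), int(0.6 * M)),
        ("chr12", int(2.6 * M), int(3.0 * M)),
        ("chr12", int(9.2 * M), int(9.6 * M)),
        ("chr2", int(1.8 * M), int(2.2 * M)),
        ("chr2", int(3.6 * M), int(4.0 * M)),
    ]

    def model(regions: Sequence[tuple[str, int, int]]) -> ContactModel:
        return ContactModel(
            viewpoint=(vp.chrom, vp.pos),
            decay_exponent=1.0,
            domain_intervals=[domain],
            enriched_regions=[EnrichedRegion(c, s, e, fold=8.0) for c, s, e in regions],
            trans_rate=0.15,
        )

    models = {
        "lymphoid": {"A": model(lymphoid_regions), "B": model(lymphoid_regions)},
        "brain": {"A": model(brain_regions), "B": model(brain_regions)},
        # domain decay only: the clean setting for boundary localization
        "domain_only": {"A": model([]), "B": model([])},
    }
    expression = simulate_expression_track(
        lymphoid_regions, chroms, 0.4, 0.1, seed=seed + 3
    )
    return Scenario(
        hap=hap,
        dbs=dbs,
        viewpoint=vp,
        se_viewpoint=vp_se,
        models=models,
        expression=expression,
        active_regions=lymphoid_regions,
        seed=seed,
    )


def compartment_scenario(
    seed: int = 1,
    cis_length: int = 6_000_000,
    trans_length: int = 78_000_000,
    read_len: int = 36,
    primer_len: int = 20,
) -> Scenario:
    """The sparse-background layout used for domainogram calling and activity.

    The large trans chromosome dilutes trans captures so that at 1e5 reads
    the per-allele background coverage of trans fragment ends is ~0.1,
    giving the binomial window model a well-separated null.  Six 1 Mb
    lymphoid enriched regions (fold 8) and five disjoint "brain" regions are
    placed in trans; the expression track is active over the lymphoid
    regions.
    """
    chroms = {"chr12": cis_length, "chrX": trans_length}
    hap = generate_haplotypes(GenomeSpec(chroms, n_snps=10), seed=seed)
    hap, vp = design_pe_viewpoint(
        hap, "chr12", cis_length // 2, name="3RR-like",
        primer_len=primer_len, read_len=read_len, seed=seed + 1,
    )
    cap_len = read_len - primer_len
    dbs = {
        "A": build_fragment_end_db(hap.seq_a, map_prefix_len=cap_len),
        "B": build_fragment_end_db(hap.seq_b, map_prefix_len=cap_len),
    }
    M = 1_000_000
    domain = DomainInterval("chr12", int(1.5 * M), int(4.5 * M), attenuation=0.1)
    lymphoid_regions = [("chrX", c * M, (c + 1) * M) for c in (5, 15, 25, 40, 55, 70)]
    brain_regions = [("chrX", c * M, (c + 1) * M) for c in (10, 20, 35, 50, 65)]

    def model(regions: Sequence[tuple[str, int, int]]) -> ContactModel:
        return ContactModel(
            viewpoint=(vp.chrom, vp.pos),
            decay_exponent=1.0,
            domain_intervals=[domain],
            enriched_regions=[EnrichedRegion(c, s, e, fold=8.0) for c, s, e in regions],
            trans_rate=0.08,
        )

    models = {
        "lymphoid": {"A": model(lymphoid_regions), "B": model(lymphoid_regions)},
        "brain": {"A": model(brain_regions), "B": model(brain_regions)},
    }
    expression = simulate_expression_track(
        lymphoid_regions, chroms, 0.4, 0.1, seed=seed + 3
    )
    return Scenario(
        hap=hap,
        dbs=dbs,
        viewpoint=vp,
        se_viewpoint=None,
        models=models,
        expression=expression,
        active_regions=lymphoid_regions,
        seed=seed,
    )
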