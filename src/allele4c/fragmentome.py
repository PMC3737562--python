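"""In-silico double digestion and the 4C fragment-end database.

4C-seq quantifies ligation products between a fixed "viewpoint" restriction
fragment and the rest of the genome.  The mappable unit is the *fragment
end*: the stretch of a first-cutter (HindIII) fragment running from its
boundary to the nearest internal second-cutter (DpnII) site.  This module
performs the in-silico digestion, builds the database of fragment ends with
blind/uniqueness annotation, and detects restriction-site polymorphisms
(RFLPs) between two haplotypes, which make single-end 4C assays
allele-selective.

Coordinates are 0-based half-open throughout.  Cut offsets follow enzyme
chemistry: HindIII cuts A^AGCTT (offset 1), DpnII cuts ^GATC (offset 0), so
fragment boundaries land on cut positions and the downstream fragment starts
with the recognition-site remnant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: recognition site and cut offset for the enzymes used by the assay
RESTRICTION_ENZYMES: dict[str, tuple[str, int]] = {
    "HindIII": ("AAGCTT", 1),
    "DpnII": ("GATC", 0),
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: default length of the mapping prefix used for uniqueness and exact lookup
DEFAULT_MAP_PREFIX_LEN = 36


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def resolve_enzyme(enzyme: str | tuple[str, int]) -> tuple[str, str, int]:
    """Return ``(name, site, cut_offset)`` for an enzyme name or (site, offset) pair."""
    if isinstance(enzyme, str):
        if enzyme not in RESTRICTION_ENZYMES:
            raise KeyError(
                f"unknown enzyme {enzyme!r}; known: {sorted(RESTRICTION_ENZYMES)}"
            )
        site, offset = RESTRICTION_ENZYMES[enzyme]
        return enzyme, site, offset
    site, offset = enzyme
    return site, site.upper(), offset


def _validate_sequence(sequence: str) -> None:
    allowed = set("ACGT")
    for i, ch in enumerate(sequence):
        if ch not in allowed:
            raise ValueError(
                f"non-ACGT character {ch!r} at position {i}; digestion requires "
                "an unambiguous uppercase nucleotide sequence"
            )


def find_sites(sequence: str, site: str) -> list[int]:
    """All (possibly overlapping) occurrence positions of ``site`` in ``sequence``."""
    hits = []
    pos = sequence.find(site)
    while pos != -1:
        hits.append(pos)
        pos = sequence.find(site, pos + 1)
    return hits


def digest(sequence: str, recognition_site: str, cut_offset: int) -> list[tuple[int, int]]:
    """Cut ``sequence`` at every occurrence of ``recognition_site``.

    Returns the ordered list of fragment intervals (0-based half-open) whose
    boundaries are ``occurrence + cut_offset`` for every occurrence, plus the
    sequence ends.  Overlapping occurrences are all honoured.
    """
    if not recognition_site:
        raise ValueError("recognition site must be non-empty")
    _validate_sequence(sequence)
    _validate_sequence(recognition_site)
    cuts = sorted({p + cut_offset for p in find_sites(sequence, recognition_site)})
    bounds = [0] + [c for c in cuts if 0 < c < len(sequence)] + [len(sequence)]
    bounds = sorted(set(bounds))
    return list(zip(bounds[:-1], bounds[1:]))


@dataclass
class FragmentMap:
    """First-cutter fragments per chromosome, tiling each chromosome exactly."""

    fragments: dict[str, list[tuple[int, int]]]
    enzyme: str = "HindIII"

    #: global fragment index offsets, chromosome order preserved
    _offsets: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        off = 0
        self._offsets = {}
        for chrom, frags in self.fragments.items():
            self._offsets[chrom] = off
            off += len(frags)

    @classmethod
    def from_sequences(
        cls, sequences: Mapping[str, str], enzyme: str | tuple[str, int] = "HindIII"
    ) -> "FragmentMap":
        name, site, offset = resolve_enzyme(enzyme)
        frags = {}
        for chrom, seq in sequences.items():
            if len(seq) < len(site):
                warnings.warn(
                    f"chromosome {chrom} shorter than the recognition site; empty map"
                )
                frags[chrom] = []
                continue
            frags[chrom] = digest(seq, site, offset)
        return cls(fragments=frags, enzyme=name)

    @property
    def n_fragments(self) -> int:
        return sum(len(v) for v in self.fragments.values())

    def frag_id_at(self, chrom: str, pos: int) -> int:
        """Global id of the fragment containing (chrom, pos)."""
        frags = self.fragments[chrom]
        starts = [s for s, _ in frags]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= frags[i][1]:
            raise ValueError(f"position {chrom}:{pos} outside fragment map")
        return self._offsets[chrom] + i

    def bounds(self, frag_id: int) -> tuple[str, int, int]:
        for chrom, frags in self.fragments.items():
            off = self._offsets[chrom]
            if off <= frag_id < off + len(frags):
                s, e = frags[frag_id - off]
                return chrom, s, e
        raise KeyError(frag_id)


@dataclass
class RFLPSite:
    """A SNP that creates a second-cutter site on exactly one haplotype."""

    chrom: str
    pos: int
    base_a: str
    base_b: str
    gained_on: str  # 'A' or 'B': the allele carrying the extra site
    site_pos: int  # start of the gained recognition site

    @property
    def lost_on(self) -> str:
        return "B" if self.gained_on == "A" else "A"


class FragmentEndDB:
    """Database of 4C fragment ends over one haplotype.

    ``ends`` is a DataFrame with columns ``end_id, frag_id, side, chrom,
    start, end, blind, unique, sequence``.  ``sequence`` is stored on the
    plus strand; reads arriving from the 3' side of a fragment are matched
    against the reverse complement at mapping time via :meth:`mapping_index`
    rather than duplicated here.
    """

    def __init__(
        self,
        ends: pd.DataFrame,
        fragment_map: FragmentMap,
        map_prefix_len: int,
        first_cutter: str = "HindIII",
        second_cutter: str = "DpnII",
    ) -> None:
        self.ends = ends.reset_index(drop=True)
        self.fragment_map = fragment_map
        self.map_prefix_len = int(map_prefix_len)
        self.first_cutter = first_cutter
        self.second_cutter = second_cutter
        self._index: dict[str, list[int]] | None = None

    def __len__(self) -> int:
        return len(self.ends)

    # -- derived views ----------------------------------------------------
    @property
    def analyzable(self) -> np.ndarray:
        """Boolean mask of ends usable for profile statistics (unique, non-blind)."""
        return (self.ends["unique"] & ~self.ends["blind"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.ends["start"] + self.ends["end"]) / 2.0).to_numpy()

    @property
    def n_blind(self) -> int:
        return int(self.ends["blind"].sum())

    @property
    def n_nonunique(self) -> int:
        return int((~self.ends["unique"]).sum())

    def oriented_sequence(self, end_id: int) -> str:
        """End sequence read inward from the fragment boundary (as a read would)."""
        row = self.ends.iloc[end_id]
        return row["sequence"] if row["side"] == "5p" else revcomp(row["sequence"])

    def mapping_key(self, end_id: int) -> str:
        return self.oriented_sequence(end_id)[: self.map_prefix_len]

    def mapping_index(self) -> dict[str, list[int]]:
        """Exact-lookup index: mapping prefix -> list of end ids sharing it."""
        if self._index is None:
            idx: dict[str, list[int]] = {}
            for end_id in range(len(self.ends)):
                idx.setdefault(self.mapping_key(end_id), []).append(end_id)
            self._index = idx
        return self._index

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.ends.to_csv(path, sep="\t", index=False)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.ends.itertuples():
                fh.write(f">end{row.end_id}|{row.chrom}:{row.start}-{row.end}|{row.side}\n")
                fh.write(row.sequence + "\n")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        fragment_map: FragmentMap,
        map_prefix_len: int = DEFAULT_MAP_PREFIX_LEN,
    ) -> "FragmentEndDB":
        ends = pd.read_csv(path, sep="\t")
        return cls(ends, fragment_map, map_prefix_len)


def build_fragment_end_db(
    sequences: Mapping[str, str],
    first_cutter: str | tuple[str, int] = "HindIII",
    second_cutter: str | tuple[str, int] = "DpnII",
    map_prefix_len: int = DEFAULT_MAP_PREFIX_LEN,
) -> FragmentEndDB:
    """Digest ``sequences`` and assemble the fragment-end database.

    Every fragment flanked by a first-cutter boundary contributes an end per
    such boundary.  An end's sequence runs from the fragment boundary to the
    nearest internal second-cutter cut, or to the opposite boundary when the
    fragment is *blind* (no internal second-cutter site).  Uniqueness is
    computed over oriented mapping prefixes of ``map_prefix_len`` bp.
    """
    if map_prefix_len < 12:
        raise ValueError("map_prefix_len must be >= 12")
    name1, site1, off1 = resolve_enzyme(first_cutter)
    name2, site2, off2 = resolve_enzyme(second_cutter)
    fmap = FragmentMap.from_sequences(sequences, (site1, off1))
    fmap.enzyme = name1

    records = []
    end_id = 0
    frag_id = 0
    for chrom, seq in sequences.items():
        frags = fmap.fragments.get(chrom, [])
        for fs, fe in frags:
            fragment = seq[fs:fe]
            cuts = [
                fs + p + off2
                for p in find_sites(fragment, site2)
                if 0 < p + off2 < len(fragment)
            ]
            blind = len(cuts) == 0
            # a fragment end exists only at first-cutter boundaries, so
            # chromosome-terminal fragments contribute a single end
            if fs > 0:
                e5 = cuts[0] if cuts else fe
                records.append(
                    (end_id, frag_id, "5p", chrom, fs, e5, blind, seq[fs:e5])
                )
                end_id += 1
            if fe < len(seq):
                s3 = cuts[-1] if cuts else fs
                records.append(
                    (end_id, frag_id, "3p", chrom, s3, fe, blind, seq[s3:fe])
                )
                end_id += 1
            frag_id += 1

    ends = pd.DataFrame.from_records(
        records,
        columns=["end_id", "frag_id", "side", "chrom", "start", "end", "blind", "sequence"],
    )
    # uniqueness over oriented mapping prefixes
    if len(ends):
        keys = [
            (row.sequence if row.side == "5p" else revcomp(row.sequence))[:map_prefix_len]
            for row in ends.itertuples()
        ]
        counts = pd.Series(keys).value_counts()
        ends["unique"] = [counts[k] == 1 for k in keys]
    else:
        ends["unique"] = pd.Series([], dtype=bool)
    ends = ends[
        ["end_id", "frag_id", "side", "chrom", "start", "end", "blind", "unique", "sequence"]
    ]
    return FragmentEndDB(ends, fmap, map_prefix_len, name1, name2)


def detect_rflp(
    snps: Iterable[Sequence],
    hap_a: Mapping[str, str],
    hap_b: Mapping[str, str],
    second_cutter: str | tuple[str, int] = "DpnII",
) -> list[RFLPSite]:
    """SNPs that create a second-cutter site on exactly one haplotype.

    For each SNP ``(chrom, pos, base_a, base_b)`` the window of +-(site_len-1)
    bases around the SNP is scanned in both haplotypes; the SNP is reported
    iff the recognition site occurs in one window and not the other.
    """
    _, site, _ = resolve_enzyme(second_cutter)
    k = len(site)
    out = []
    for snp in snps:
        chrom, pos, base_a, base_b = snp[0], snp[1], snp[2], snp[3]
        lo = max(0, pos - k + 1)
        hi = pos + k
        win_a = hap_a[chrom][lo:hi]
        win_b = hap_b[chrom][lo:hi]
        in_a = site in win_a
        in_b = site in win_b
        if in_a == in_b:
            continue
        gained = "A" if in_a else "B"
        win = win_a if in_a else win_b
        site_pos = lo + win.find(site)
        out.append(RFLPSite(chrom, pos, base_a, base_b, gained, site_pos))
    return out
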