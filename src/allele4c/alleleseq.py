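"""Allele assignment, primer trimming and exact mapping to fragment ends.

The paired-end strategy (PE-4Cseq) sequences two reads per ligation product:
read 1 starts in the viewpoint primer (P1) and runs across the ligation
junction into the captured fragment end, while read 2 (P2) stays inside the
viewpoint fragment and covers a known SNP, so each captured contact can be
attributed to one parental allele.  The single-end strategy (SE-4Cseq)
instead relies on a restriction-fragment-length polymorphism: an extra
second-cutter site on one allele severs the primer from the ligation
junction, so only the other allele yields mappable product.

Mapping is exact (no mismatches): a trimmed read counts for a fragment end
iff it equals that end's oriented mapping prefix, via a hash lookup.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .fragmentome import FragmentEndDB, FragmentMap, RFLPSite

#: minimum post-trim length for exact mapping; shorter reads are not
#: genome-unique even in toy genomes
MIN_MAPPING_LEN = 12

ALLELES = ("A", "B")


@dataclass
class ViewpointSpec:
    """Definition of a 4C viewpoint and its allele-discrimination strategy.

    ``p1_start:p1_end`` is the region whose sequence (``p1_seq``) every valid
    read 1 must begin with; it ends at the first-cutter boundary of the
    viewpoint fragment so the remainder of the read is captured sequence.
    For the PE strategy ``p2_start:p2_end`` locates read 2 inside the
    viewpoint fragment with the allele-informative SNP at ``snp_offset``.
    For the SE strategy ``rflp`` names the allele-selective second-cutter
    polymorphism and ``retained_allele`` the allele the assay reads.
    """

    name: str
    chrom: str
    pos: int
    strategy: str  # 'PE' | 'SE'
    p1_start: int
    p1_end: int
    p1_seq: str
    p2_start: Optional[int] = None
    p2_end: Optional[int] = None
    snp_offset: Optional[int] = None
    base_a: Optional[str] = None
    base_b: Optional[str] = None
    rflp: Optional[RFLPSite] = None
    retained_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strategy not in ("PE", "SE"):
            raise ValueError("strategy must be 'PE' or 'SE'")
        if self.strategy == "PE":
            missing = [
                f
                for f in ("p2_start", "p2_end", "snp_offset", "base_a", "base_b")
                if getattr(self, f) is None
            ]
            if missing:
                raise ValueError(f"PE viewpoint requires {missing}")
        else:
            if self.rflp is None:
                raise ValueError("SE viewpoint requires an RFLPSite reference")

    def expected_base(self, allele: str) -> str:
        return {"A": self.base_a, "B": self.base_b}[allele]

    def validate(self, fragment_map: FragmentMap) -> None:
        """Check that P1 (and P2, if present) lie in the same first-cutter fragment."""
        f1 = fragment_map.frag_id_at(self.chrom, self.p1_start)
        if fragment_map.frag_id_at(self.chrom, self.p1_end - 1) != f1:
            raise ValueError("P1 spans a first-cutter boundary")
        if self.p2_start is not None:
            f2 = fragment_map.frag_id_at(self.chrom, self.p2_start)
            if f2 != f1 or fragment_map.frag_id_at(self.chrom, self.p2_end - 1) != f1:
                raise ValueError("P1 and P2 must lie within the same fragment")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ViewpointSpec":
        d = dict(d)
        if d.get("rflp") is not None:
            d["rflp"] = RFLPSite(**d["rflp"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ViewpointSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SplitPools:
    """Result of PE allele demultiplexing: read-1 pools keyed by allele tag."""

    pools: dict[str, list[tuple[str, str]]]
    reasons: Counter = field(default_factory=Counter)

    @property
    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.pools.items()}


def split_by_snp(
    read_pairs: Iterable[tuple[str, str, str]], vp: ViewpointSpec
) -> SplitPools:
    """Partition read pairs into allele pools A / B / ambiguous.

    Assignment depends only on the read-2 base at ``vp.snp_offset`` (exact,
    case-insensitive match to the expected allele base).  Pairs whose read 2
    is too short to cover the SNP are routed to the ambiguous pool with a
    distinct reason code.
    """
    if vp.strategy != "PE":
        raise ValueError("split_by_snp applies to PE viewpoints only")
    off = vp.snp_offset
    ba = vp.base_a.upper()
    bb = vp.base_b.upper()
    pools: dict[str, list[tuple[str, str]]] = {"A": [], "B": [], "ambiguous": []}
    reasons: Counter = Counter()
    for read_id, seq1, seq2 in read_pairs:
        if len(seq2) <= off:
            pools["ambiguous"].append((read_id, seq1))
            reasons["read2-too-short"] += 1
            continue
        base = seq2[off].upper()
        if base == ba:
            pools["A"].append((read_id, seq1))
        elif base == bb:
            pools["B"].append((read_id, seq1))
        else:
            pools["ambiguous"].append((read_id, seq1))
            reasons["snp-base-no-match"] += 1
    return SplitPools(pools=pools, reasons=reasons)


def enforce_se_allele(
    reads: Sequence[tuple[str, str]], vp: ViewpointSpec, rflp: Optional[RFLPSite] = None
) -> tuple[list[tuple[str, str]], str, str]:
    """Tag SE reads with the retained allele.

    No sequence filtering happens here: the selectivity is built into the
    assay, because on the allele that gained the second-cutter site the
    primer is severed from the ligation junction, so its products fail the
    exact viewpoint-sequence match downstream.  Returns the reads, the
    retained allele label and a provenance note.
    """
    rflp = rflp if rflp is not None else vp.rflp
    if rflp is None:
        raise ValueError("SE allele enforcement requires an RFLPSite")
    retained = rflp.lost_on
    note = (
        f"viewpoint {vp.name}: second-cutter site gained on allele "
        f"{rflp.gained_on} at {rflp.chrom}:{rflp.site_pos}; analysis restricted "
        f"to allele {retained}"
    )
    return list(reads), retained, note


def trim_primer(
    read_seq: str, vp: ViewpointSpec, min_len: int = MIN_MAPPING_LEN
) -> tuple[Optional[str], str]:
    """Strip the viewpoint sequence from a read 1.

    The read must begin with ``vp.p1_seq`` exactly; otherwise it is rejected
    with reason ``primer-mismatch``.  Remainders shorter than ``min_len`` are
    rejected with reason ``too-short``.
    """
    if not read_seq.startswith(vp.p1_seq):
        return None, "primer-mismatch"
    rest = read_seq[len(vp.p1_seq):]
    if len(rest) < min_len:
        return None, "too-short"
    return rest, "ok"


@dataclass
class CaptureTable:
    """Per-fragment-end capture counts for one (viewpoint, allele, sample).

    ``counts`` is aligned with ``db.ends``; only unique, non-blind ends ever
    receive counts.  ``totals`` is a full accounting of the input reads, so
    that mapped + unmapped + discarded categories always sum to the input.
    """

    counts: np.ndarray
    totals: dict[str, int]
    viewpoint: str
    allele: str
    sample: str = ""
    db: Optional[FragmentEndDB] = None

    @property
    def mapped(self) -> int:
        return self.totals["mapped"]

    def check_accounting(self, n_input: Optional[int] = None) -> None:
        cats = [v for k, v in self.totals.items() if k != "input"]
        if sum(cats) != self.totals["input"]:
            raise AssertionError(f"accounting identity violated: {self.totals}")
        if n_input is not None and self.totals["input"] != n_input:
            raise AssertionError("input total mismatch")
        if int(self.counts.sum()) != self.totals["mapped"]:
            raise AssertionError("mapped total != sum of per-end counts")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"end_id": np.arange(len(self.counts)), "count": self.counts})
        with open(path, "w") as fh:
            fh.write(f"# viewpoint={self.viewpoint} allele={self.allele} sample={self.sample}\n")
            fh.write("# totals=" + json.dumps(self.totals) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, db: Optional[FragmentEndDB] = None) -> "CaptureTable":
        meta: dict[str, str] = {}
        totals: dict[str, int] = {}
        with open(path) as fh:
            line = fh.readline()
            for part in line.lstrip("# ").split():
                k, _, v = part.partition("=")
                meta[k] = v
            totals = json.loads(fh.readline().lstrip("# ").partition("=")[2])
            df = pd.read_csv(fh, sep="\t")
        return cls(
            counts=df["count"].to_numpy(),
            totals=totals,
            viewpoint=meta.get("viewpoint", ""),
            allele=meta.get("allele", ""),
            sample=meta.get("sample", ""),
            db=db,
        )


def map_to_fragment_ends(
    reads: Sequence[tuple[str, str]],
    db: FragmentEndDB,
    viewpoint: str = "",
    allele: str = "",
    sample: str = "",
    extra_totals: Optional[Mapping[str, int]] = None,
) -> CaptureTable:
    """Exact mapping of trimmed reads against the fragment-end database.

    A read increments exactly one fragment end iff its sequence equals that
    end's oriented mapping prefix (reads longer than the prefix are compared
    on the prefix).  Reads matching no end are unmapped; reads matching more
    than one end are discarded as non-unique; blind ends never accumulate
    counts.  ``extra_totals`` lets the caller fold upstream rejection
    categories (primer mismatch, allele ambiguity, ...) into the accounting.
    """
    if len(db) == 0:
        raise ValueError("empty fragment-end database")
    index = db.mapping_index()
    blind = db.ends["blind"].to_numpy()
    L = db.map_prefix_len
    counts = np.zeros(len(db), dtype=np.int64)
    mapped = unmapped = multi = blind_discarded = 0
    for _read_id, seq in reads:
        key = seq[:L]
        hits = index.get(key)
        if not hits:
            unmapped += 1
        elif len(hits) > 1:
            multi += 1
        elif blind[hits[0]]:
            blind_discarded += 1
        else:
            counts[hits[0]] += 1
            mapped += 1
    totals = {
        "input": len(reads),
        "mapped": mapped,
        "unmapped": unmapped,
        "multi_discarded": multi,
        "blind_discarded": blind_discarded,
    }
    if extra_totals:
        totals["input"] += sum(extra_totals.values())
        totals.update(extra_totals)
    return CaptureTable(
        counts=counts, totals=totals, viewpoint=viewpoint, allele=allele,
        sample=sample, db=db,
    )


def demultiplex_and_map(
    read_pairs: Sequence[tuple[str, str, str]],
    vp: ViewpointSpec,
    dbs: Mapping[str, FragmentEndDB],
    sample: str = "",
) -> dict[str, CaptureTable]:
    """PE pipeline step: split by SNP, trim P1, map each pool on its allele's database.

    Ambiguous-allele pairs are discarded from both profiles (allele purity
    over yield); their count is charged to allele A's accounting so that the
    category totals of the two tables sum to the number of input pairs.
    """
    split = split_by_snp(read_pairs, vp)
    tables: dict[str, CaptureTable] = {}
    for i, allele in enumerate(ALLELES):
        trimmed: list[tuple[str, str]] = []
        rejects: Counter = Counter()
        for read_id, seq1 in split.pools[allele]:
            t, reason = trim_primer(seq1, vp)
            if t is None:
                rejects[reason.replace("-", "_")] += 1
            else:
                trimmed.append((read_id, t))
        extra = dict(rejects)
        if i == 0:
            extra["ambiguous_allele"] = len(split.pools["ambiguous"])
        tables[allele] = map_to_fragment_ends(
            trimmed, dbs[allele], viewpoint=vp.name, allele=allele,
            sample=sample, extra_totals=extra,
        )
    return tables


def map_se_reads(
    reads: Sequence[tuple[str, str]],
    vp: ViewpointSpec,
    dbs: Mapping[str, FragmentEndDB],
    sample: str = "",
) -> CaptureTable:
    """SE pipeline step: tag with the retained allele, trim, map."""
    tagged, retained, _note = enforce_se_allele(reads, vp)
    trimmed = []
    rejects: Counter = Counter()
    for read_id, seq in tagged:
        t, reason = trim_primer(seq, vp)
        if t is None:
            rejects[reason.replace("-", "_")] += 1
        else:
            trimmed.append((read_id, t))
    return map_to_fragment_ends(
        trimmed, dbs[retained], viewpoint=vp.name, allele=retained,
        sample=sample, extra_totals=dict(rejects),
    )


# -- FASTQ ingestion ------------------------------------------------------

def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Load a FASTQ file as (read_id, sequence) tuples."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> list[tuple[str, str, str]]:
    """Load an R1/R2 FASTQ pair as (read_id, seq1, seq2) tuples."""
    out = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(r1), "fastq"), SeqIO.parse(str(r2), "fastq"), strict=True
    ):
        if rec1.id != rec2.id:
            raise ValueError(f"unsynchronized FASTQ pair at {rec1.id} / {rec2.id}")
        out.append((rec1.id, str(rec1.seq), str(rec2.seq)))
    return out
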