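"""SeEN-seq library design and positional enrichment.

SeEN-seq (Selected Engagement on Nucleosome sequencing) tiles a TF motif at
1-bp intervals across a motif-free nucleosome positioning backbone, assembles
the variant pool into nucleosomes, separates TF-bound from unbound particles,
and reads out a per-position relative enrichment:

    e_i = (b_i / sum b) / (u_i / sum u)

the fold change between library-size-normalised bound and unbound read
counts at tiling position i. Profiles are conventionally max-normalised so
the highest position equals 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import revcomp, validate_dna
from .nucframe import NucFrame, pos_to_shl

__all__ = [
    "MotifSpec",
    "BackboneSpec",
    "VariantLibrary",
    "ReadCounts",
    "EnrichmentProfile",
    "design_variants",
    "flank_and_digest",
    "count_reads",
    "enrichment",
    "normalize_profile",
]

logger = logging.getLogger(__name__)

ECORV_SITE = "GATATC"


def occurs_on_either_strand(motif: str, seq: str) -> bool:
    return motif in seq or revcomp(motif) in seq


def count_occurrences(motif: str, seq: str) -> int:
    """Occurrences of motif on both strands (overlap-aware).

    A palindromic motif (e.g. CACGTG) is counted once per duplex site.
    """
    def _count(m: str, s: str) -> int:
        n, start = 0, 0
        while True:
            i = s.find(m, start)
            if i < 0:
                return n
            n += 1
            start = i + 1

    rc = revcomp(motif)
    n = _count(motif, seq)
    if rc != motif:
        n += _count(rc, seq)
    return n


@dataclass(frozen=True)
class MotifSpec:
    """A TF binding motif: the recognition core and the full inserted cassette."""

    name: str
    core: str
    full_insert: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "core", validate_dna(self.core, "core"))
        object.__setattr__(self, "full_insert", validate_dna(self.full_insert, "full_insert"))
        if self.core not in self.full_insert:
            raise ValueError("core must be a substring of full_insert")


#: The JASPAR E-box cassette used throughout: core CACGTG within GGCACGTGTC.
EBOX = MotifSpec(name="E-box", core="CACGTG", full_insert="GGCACGTGTC")


@dataclass(frozen=True)
class BackboneSpec:
    """A nucleosome-positioning backbone guaranteed free of forbidden motifs."""

    sequence: str
    forbidden_motifs: tuple[str, ...] = ("CACGTG",)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_dna(self.sequence, "backbone"))
        object.__setattr__(
            self, "forbidden_motifs", tuple(validate_dna(m, "motif") for m in self.forbidden_motifs)
        )
        for m in self.forbidden_motifs:
            if occurs_on_either_strand(m, self.sequence):
                raise ValueError(f"backbone contains forbidden motif {m}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class VariantLibrary:
    """Tiling-position -> construct sequence map, plus optional spike-in."""

    entries: dict[int, str]
    motif: MotifSpec
    spike_in: str | None = None
    frame: NucFrame | None = field(default_factory=NucFrame)
    excluded: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.entries.values()}
        if len(lengths) > 1:
            raise ValueError("all constructs must have equal length")

    def positions(self) -> list[int]:
        return sorted(self.entries)

    def shl(self, position: int) -> float:
        """SHL of the motif-core centroid for the variant at ``position``."""
        if self.frame is None:
            return float("nan")
        core_off = self.motif.full_insert.index(self.motif.core)
        return pos_to_shl(self.frame, position + core_off, len(self.motif.core))

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq(seq), id=f"variant_{pos:03d}", description=f"tiling_start={pos}")
            for pos, seq in sorted(self.entries.items())
        ]
        if self.spike_in is not None:
            recs.append(SeqRecord(Seq(self.spike_in), id="spike_in", description="competitor"))
        seqio_write(recs, path, "fasta")


def design_variants(backbone: BackboneSpec, motif: MotifSpec = EBOX) -> VariantLibrary:
    """Tile ``motif.full_insert`` at 1-bp intervals across the backbone.

    One variant per start s in [0, len(backbone) - len(full_insert)], each
    equal to the backbone with the cassette substituted at s. Variants whose
    substitution junction creates a second core occurrence (counting both
    strands) are excluded with a warning and recorded in ``library.excluded``.
    """
    seq = backbone.sequence
    ins = motif.full_insert
    if len(ins) > len(seq):
        raise ValueError("insert longer than backbone")
    if occurs_on_either_strand(motif.core, seq):
        raise ValueError(f"backbone contains the motif core {motif.core}")

    entries: dict[int, str] = {}
    excluded: dict[int, str] = {}
    for s in range(len(seq) - len(ins) + 1):
        var = seq[:s] + ins + seq[s + len(ins):]
        if count_occurrences(motif.core, var) == 1:
            entries[s] = var
        else:
            excluded[s] = var
    if excluded:
        warnings.warn(
            f"{len(excluded)} variant(s) excluded: substitution junction created "
            f"a second {motif.core} occurrence",
            stacklevel=2,
        )
    frame = NucFrame(length_bp=len(seq), dyad_index=len(seq) // 2) if len(seq) % 2 else None
    return VariantLibrary(entries=entries, motif=motif, frame=frame, excluded=excluded)


def flank_and_digest(variant: str, ecorv_site: str = ECORV_SITE, adapter: str = "ACGGCCAGT") -> list[str]:
    """Simulate EcoRV excision of a variant from its adapter-flanked construct.

    The synthesised construct is adapter + GATATC + variant + GATATC + adapter;
    blunt cleavage at GAT^ATC releases ATC + variant + GAT (length = variant
    length + 6). If the variant itself contains an EcoRV site the enzyme cuts
    there too; all resulting internal fragments are returned (lengths summing
    to len(variant) + 6) with a warning.
    """
    variant = validate_dna(variant, "variant") if variant else variant
    half5, half3 = ecorv_site[:3], ecorv_site[3:]  # GAT / ATC
    construct = adapter + ecorv_site + variant + ecorv_site + adapter
    cuts = [i + 3 for i in _find_all(construct, ecorv_site)]
    pieces = [construct[a:b] for a, b in zip(cuts[:-1], cuts[1:])]
    if ecorv_site in variant:
        warnings.warn("variant contains an internal EcoRV site; extra cut(s) applied", stacklevel=2)
    assert pieces and pieces[0].startswith(half3) and pieces[-1].endswith(half5)
    return pieces


def _find_all(seq: str, sub: str) -> list[int]:
    out, start = [], 0
    while True:
        i = seq.find(sub, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


@dataclass
class ReadCounts:
    """Per-variant read counts for one sample (one fraction, one replicate)."""

    label: str
    fraction: str  # "bound" or "unbound"
    replicate: str
    counts: dict[int, int]
    unassigned: int = 0
    spike_in: int = 0

    def __post_init__(self) -> None:
        if self.fraction not in ("bound", "unbound"):
            raise ValueError(f"fraction must be 'bound' or 'unbound', got {self.fraction!r}")
        if any(c < 0 for c in self.counts.values()) or self.unassigned < 0 or self.spike_in < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unassigned + self.spike_in


def _discriminating_windows(
    library: VariantLibrary, flank: int, digested: bool
) -> dict[str, int | str]:
    """Map window sequence -> variant position (or 'spike_in').

    The window is the substituted cassette plus ``flank`` bp of backbone
    context on each side, clipped to the construct; it is the minimal region
    that distinguishes tiling variants from one another.
    """
    ins_len = len(library.motif.full_insert)
    pad = 3 if digested else 0  # ATC/GAT remnants shift coordinates
    windows: dict[str, int | str] = {}
    for pos, seq in library.entries.items():
        s = seq if not digested else flank_and_digest(seq)[0]
        a = max(0, pos + pad - flank)
        b = min(len(s), pos + pad + ins_len + flank)
        w = s[a:b]
        if w in windows:
            raise ValueError(
                f"library-design error: variants {windows[w]} and {pos} share a "
                f"discriminating window; increase the flank"
            )
        windows[w] = pos
    return windows


def count_reads(
    reads,
    library: VariantLibrary,
    min_overlap: int = 8,
    digested: bool = True,
) -> ReadCounts:
    """Assign reads to tiling variants by exact discriminating-window match.

    Each read is assigned to the unique variant whose discriminating window
    (the substituted region +/- ``min_overlap`` bp of flank) occurs in the
    read on either strand. Reads matching zero or more than one window are
    counted as unassigned; reads identical to the spike-in competitor (either
    strand) are counted separately.

    ``reads`` may be an iterable of strings or Biopython SeqRecords.
    """
    if not library.entries:
        raise ValueError("library is empty")
    windows = _discriminating_windows(library, min_overlap, digested)
    spike = library.spike_in
    if digested and spike is not None:
        spike = flank_and_digest(spike)[0]

    # every discriminating window contains the cassette exactly once, so a
    # window can only match a read where the cassette itself matches; anchor
    # candidate lookups at cassette occurrences instead of scanning all windows
    insert = library.motif.full_insert
    anchor_shapes = sorted({(w.find(insert), len(w)) for w in windows})
    counts = {pos: 0 for pos in library.entries}
    unassigned = spike_count = 0
    for rec in reads:
        read = str(getattr(rec, "seq", rec)).upper()
        rc = revcomp(read)
        hits = set()
        for s in (read, rc):
            j = s.find(insert)
            while j >= 0:
                for o_w, L in anchor_shapes:
                    a = j - o_w
                    if 0 <= a and a + L <= len(s):
                        pos = windows.get(s[a: a + L])
                        if pos is not None:
                            hits.add(pos)
                j = s.find(insert, j + 1)
        if len(hits) == 1:
            counts[hits.pop()] += 1
        elif spike is not None and (read == spike or rc == spike):
            spike_count += 1
        else:
            unassigned += 1
    return ReadCounts(
        label="sample", fraction="unbound", replicate="1",
        counts=counts, unassigned=unassigned, spike_in=spike_count,
    )


@dataclass
class EnrichmentProfile:
    """Per-position relative enrichment with replicate structure.

    ``table`` columns: position, shl, one column per replicate id
    (``rep_<id>``), and ``mean``. Undefined positions (zero unbound counts
    without pseudocount) are NaN, never +/-inf.
    """

    table: pd.DataFrame
    normalized: bool = False

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    @property
    def mean(self) -> np.ndarray:
        return self.table["mean"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def enrichment(
    bound: list[ReadCounts] | ReadCounts,
    unbound: list[ReadCounts] | ReadCounts,
    pseudocount: float = 0.0,
    frame: NucFrame | None = None,
    library: VariantLibrary | None = None,
    include_special_in_totals: bool = False,
) -> EnrichmentProfile:
    """Fold change between library-size-normalised bound and unbound counts.

    Per replicate r: e_i = ((b_i + p)/sum_j (b_j + p)) / ((u_i + p)/sum_j (u_j + p)).
    Positions with zero unbound counts and zero pseudocount are NaN
    (undefined). Replicates are paired by replicate id and averaged
    arithmetically. Spike-in and unassigned reads are excluded from library
    totals unless ``include_special_in_totals``.
    """
    bound = [bound] if isinstance(bound, ReadCounts) else list(bound)
    unbound = [unbound] if isinstance(unbound, ReadCounts) else list(unbound)
    b_by_rep = {rc.replicate: rc for rc in bound}
    u_by_rep = {rc.replicate: rc for rc in unbound}
    if set(b_by_rep) != set(u_by_rep):
        raise ValueError("bound and unbound replicates do not pair up")

    positions = sorted(bound[0].counts)
    for rc in bound + unbound:
        if sorted(rc.counts) != positions:
            raise ValueError("bound and unbound must cover the same positions")

    rep_ids = sorted(b_by_rep)
    data: dict[str, np.ndarray] = {}
    for rid in rep_ids:
        b = np.array([b_by_rep[rid].counts[p] for p in positions], float) + pseudocount
        u = np.array([u_by_rep[rid].counts[p] for p in positions], float) + pseudocount
        bs, us = b.sum(), u.sum()
        if include_special_in_totals:
            bs += b_by_rep[rid].unassigned + b_by_rep[rid].spike_in
            us += u_by_rep[rid].unassigned + u_by_rep[rid].spike_in
        with np.errstate(divide="ignore", invalid="ignore"):
            e = (b / bs) / (u / us)
        e[~np.isfinite(e)] = np.nan
        n_undef = int(np.isnan(e).sum())
        if n_undef:
            logger.warning("replicate %s: %d position(s) undefined (zero unbound counts)", rid, n_undef)
        data[f"rep_{rid}"] = e

    tab = pd.DataFrame({"position": positions})
    if library is not None:
        tab["shl"] = [library.shl(p) for p in positions]
    elif frame is not None:
        tab["shl"] = [pos_to_shl(frame, p) for p in positions]
    else:
        tab["shl"] = np.nan
    for k, v in data.items():
        tab[k] = v
    tab["mean"] = tab[list(data)].mean(axis=1)
    return EnrichmentProfile(table=tab, normalized=False)


def normalize_profile(profile: EnrichmentProfile) -> EnrichmentProfile:
    """Divide all defined values by the maximum of the replicate mean.

    The highest value of the profile becomes 1. Idempotent.
    """
    tab = profile.table.copy()
    m = np.nanmax(tab["mean"].to_numpy())
    if not np.isfinite(m):
        raise ValueError("all positions undefined; cannot normalize")
    rep_cols = [c for c in tab.columns if c.startswith("rep_")]
    for c in rep_cols + ["mean"]:
        tab[c] = tab[c] / m
    return EnrichmentProfile(table=tab, normalized=True)
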