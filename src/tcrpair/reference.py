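"""IMGT-based residue coordinate system for TCR variable domains.

All downstream analyses share a single 1-based residue indexing: V-gene
residues are numbered by their IMGT alignment (gaps written as ``'.'``),
the conserved CDR3 cysteine sits at position 104, and the J-gene Phe/Trp
anchor of the ``[FW]GXG`` motif sits at position 111.  Of the CDR3 only
the flanks are indexed -- the first four residues (104-107, germline V
side) and the last four (108-111, germline J side); the hypervariable
middle is excluded from every positional analysis.

Per-position amino-acid variability is summarised by the information
content ``I = 1 - H[p] / log(20)`` where ``H`` is the Shannon entropy of
the 21-symbol probability vector (20 amino acids plus the IMGT gap).
``I`` is 1 for an invariant position, 0 for a position uniform over the
20 amino acids, and may be slightly negative when the gap symbol adds
spread beyond the 20-letter uniform (the normaliser is deliberately kept
at log 20); it is never clamped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "."
SYMBOLS = AA20 + GAP
SYMBOL_INDEX = {s: i for i, s in enumerate(SYMBOLS)}

CYS_POSITION = 104
J_ANCHOR_POSITION = 111
J_ANCHOR_MOTIF = re.compile(r"[FW]G.G")

#: IMGT region boundaries (inclusive) for the V domain, in the shared indexing.
REGIONS = (
    ("FR1", 1, 26),
    ("CDR1", 27, 38),
    ("FR2", 39, 55),
    ("CDR2", 56, 65),
    ("FR3", 66, 103),
    ("CDR3-flank", 104, 111),
    ("FR4", 112, 128),
)


def region_of(position: int) -> str:
    for name, lo, hi in REGIONS:
        if lo <= position <= hi:
            return name
    return "FR4" if position > 111 else "FR1"


class ReferenceError(ValueError):
    """Malformed or inconsistent germline reference input."""


class ClonotypeExcluded(ValueError):
    """Raised when a clonotype cannot be indexed (e.g. CDR3 shorter than 8 aa)."""


@dataclass
class GeneRecord:
    chain: str          # 'alpha' | 'beta'
    seg_class: str      # 'V' | 'J'
    name: str           # gene name, allele suffix stripped
    allele: str         # e.g. '01'
    gapped_seq: str     # IMGT-gapped amino acids, '.' = gap
    flags: list[str] = field(default_factory=list)

    @property
    def ungapped(self) -> str:
        return self.gapped_seq.replace(GAP, "")

    def j_anchor_offset(self) -> int:
        """0-based offset of the [FW]GXG motif start within the ungapped J sequence."""
        m = J_ANCHOR_MOTIF.search(self.ungapped)
        if m is None:
            raise ReferenceError(f"J gene {self.name} lacks the [FW]GXG anchor motif")
        return m.start()

    def positions(self) -> dict[int, str]:
        """Map IMGT position -> residue (or gap) covered by this record."""
        if self.seg_class == "V":
            return {i + 1: aa for i, aa in enumerate(self.gapped_seq)}
        start = J_ANCHOR_POSITION - self.j_anchor_offset()
        return {start + i: aa for i, aa in enumerate(self.ungapped)}


class GeneReference:
    """Collection of IMGT-gapped germline V and J amino-acid sequences."""

    def __init__(self, records: list[GeneRecord]):
        self.records = records
        self._by_key: dict[tuple[str, str, str], list[GeneRecord]] = {}
        for rec in records:
            self._by_key.setdefault((rec.chain, rec.seg_class, rec.name), []).append(rec)
        self._validate()

    def _validate(self) -> None:
        for rec in self.records:
            if rec.chain not in ("alpha", "beta"):
                raise ReferenceError(f"unknown chain {rec.chain!r} in record {rec.name}")
            if rec.seg_class not in ("V", "J"):
                raise ReferenceError(f"unknown segment class {rec.seg_class!r} in record {rec.name}")
            bad = set(rec.gapped_seq) - set(SYMBOLS)
            if bad:
                raise ReferenceError(f"record {rec.name}: invalid symbols {sorted(bad)}")
            if rec.seg_class == "V":
                if len(rec.gapped_seq) >= CYS_POSITION:
                    aa104 = rec.gapped_seq[CYS_POSITION - 1]
                    if aa104 != GAP and aa104 != "C":
                        rec.flags.append("missing-Cys104")
                        logger.warning("V gene %s has %s at IMGT position 104 (expected Cys)",
                                       rec.name, aa104)
            else:
                rec.j_anchor_offset()  # raises when absent

    def get(self, chain: str, seg_class: str, name: str) -> list[GeneRecord]:
        key = (chain, seg_class, strip_allele(name))
        if key not in self._by_key:
            raise KeyError(f"gene {name} ({chain} {seg_class}) not in reference")
        return self._by_key[key]

    def genes(self, chain: str, seg_class: str) -> list[str]:
        return sorted({k[2] for k in self._by_key if k[0] == chain and k[1] == seg_class})

    def __len__(self) -> int:
        return len(self.records)


def strip_allele(name: str) -> str:
    return name.split("*")[0]


def load_gene_reference(path) -> GeneReference:
    """Read a germline reference from TSV or gapped FASTA.

    TSV dialect: tab-separated with header columns ``chain``, ``class``,
    ``name``, ``gapped_seq`` (optional ``allele``); ``#`` comments allowed.
    FASTA dialect: ``>name|chain|class`` headers, gaps kept as ``'.'``.
    Duplicate (chain, class, name, allele) entries are rejected.
    """
    path = str(path)
    with open(path) as fh:
        text = fh.read()
    records: list[GeneRecord] = []
    if text.lstrip().startswith(">"):
        name = None
        seq_lines: list[str] = []
        header_line = 0
        for ln, line in enumerate(text.splitlines(), 1):
            if line.startswith(">"):
                if name is not None:
                    records.append(_fasta_record(name, "".join(seq_lines), header_line))
                name, seq_lines, header_line = line[1:].strip(), [], ln
            elif line.strip():
                seq_lines.append(line.strip())
        if name is not None:
            records.append(_fasta_record(name, "".join(seq_lines), header_line))
    else:
        lines = [l for l in text.splitlines()]
        header = None
        for ln, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                for col in ("chain", "class", "name", "gapped_seq"):
                    if col not in header:
                        raise ReferenceError(f"reference TSV missing column {col!r}")
                continue
            if len(parts) < len(header):
                raise ReferenceError(f"unparsable reference record at line {ln}")
            row = dict(zip(header, parts))
            name, _, allele = row["name"].partition("*")
            records.append(GeneRecord(row["chain"], row["class"], name,
                                      row.get("allele") or allele or "01",
                                      row["gapped_seq"].upper()))
    seen = set()
    for rec in records:
        key = (rec.chain, rec.seg_class, rec.name, rec.allele)
        if key in seen:
            raise ReferenceError(f"duplicate reference record {rec.name}*{rec.allele}")
        seen.add(key)
    return GeneReference(records)


def _fasta_record(header: str, seq: str, line: int) -> GeneRecord:
    parts = header.split("|")
    if len(parts) != 3:
        raise ReferenceError(f"unparsable FASTA header at line {line}: {header!r}")
    name, chain, seg_class = parts
    gene, _, allele = name.partition("*")
    return GeneRecord(chain, seg_class, gene, allele or "01", seq.upper())


@dataclass
class ResidueIndexMap:
    """IMGT position -> residue for one chain of one clonotype."""

    chain: str
    positions: dict[int, str]
    v_gene: str
    j_gene: str
    flags: list[str] = field(default_factory=list)

    def symbol(self, position: int) -> str:
        return self.positions.get(position, GAP)

    def region(self, position: int) -> str:
        return region_of(position)


def index_clonotype_residues(clonotype, ref: GeneReference, chain: str) -> ResidueIndexMap:
    """Assign IMGT indices to one chain of a paired clonotype.

    Germline V positions come from the gene's gapped alignment; CDR3
    positions 104-107 are the first four CDR3 residues, 108-111 the last
    four; the CDR3 middle is left unindexed.  Clonotypes with CDR3 < 8 aa
    cannot supply disjoint flanks and are excluded.
    """
    v_name = clonotype.best_gene(chain, "V")
    j_name = clonotype.best_gene(chain, "J")
    cdr3 = clonotype.cdr3(chain)
    v_rec = ref.get(chain, "V", v_name)[0]
    j_rec = ref.get(chain, "J", j_name)[0]
    if len(cdr3) < 8:
        raise ClonotypeExcluded(
            f"clonotype {clonotype.clonotype_id}: CDR3 {cdr3!r} shorter than 8 aa")
    positions: dict[int, str] = {}
    flags: list[str] = []
    for i, aa in enumerate(v_rec.gapped_seq[: CYS_POSITION - 1]):
        positions[i + 1] = aa
    for i in range(4):
        positions[104 + i] = cdr3[i]
    for i in range(4):
        positions[108 + i] = cdr3[-4 + i]
    j_pos = j_rec.positions()
    expected = "".join(j_pos.get(p, GAP) for p in range(108, 112))
    if cdr3[-4:] != expected:
        flags.append("j-anchor-mismatch")
        logger.debug("clonotype %s %s: CDR3 tail %s != J germline %s",
                     clonotype.clonotype_id, chain, cdr3[-4:], expected)
    if cdr3[-1] not in "FW":
        flags.append("no-FW-anchor")
    return ResidueIndexMap(chain=chain, positions=positions,
                           v_gene=v_name, j_gene=j_name, flags=flags)


@dataclass
class PositionProfile:
    position: int
    region: str
    probs: np.ndarray           # length-21 vector over SYMBOLS
    info: float
    weighted: bool = False

    def prob(self, symbol: str) -> float:
        return float(self.probs[SYMBOL_INDEX[symbol]])


def information_content(p) -> float:
    """``I = 1 - H[p] / log(20)`` with ``0 log 0 := 0``; base-free ratio."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probability vector has negative entries")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"probability vector sums to {total}, expected 1")
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log(nz)))
    return 1.0 - h / np.log(20.0)


def build_profiles(ref: GeneReference, chain: str,
                   usage_weights: dict[str, float] | None = None) -> list[PositionProfile]:
    """Position-weight matrix over aligned germline genes of one chain.

    Without ``usage_weights`` every gene contributes equally; with weights
    each gene contributes proportionally to its usage (genes absent from
    the mapping get weight 0).  Multi-allele genes are collapsed by
    splitting the gene's weight equally across its distinct records.
    """
    records = [r for r in ref.records if r.chain == chain]
    if usage_weights is not None:
        if all(usage_weights.get(g, 0.0) == 0.0
               for g in {r.name for r in records}):
            raise ValueError("all-zero usage weights")
        if any(w < 0 for w in usage_weights.values()):
            raise ValueError("negative usage weights")
    per_gene: dict[tuple[str, str], list[GeneRecord]] = {}
    for rec in records:
        per_gene.setdefault((rec.seg_class, rec.name), []).append(rec)

    accum: dict[int, np.ndarray] = {}
    for (seg_class, gene), recs in per_gene.items():
        w_gene = 1.0 if usage_weights is None else usage_weights.get(gene, 0.0)
        for rec in recs:
            w = w_gene / len(recs)
            if w == 0:
                continue
            for pos, aa in rec.positions().items():
                vec = accum.setdefault(pos, np.zeros(len(SYMBOLS)))
                vec[SYMBOL_INDEX[aa]] += w

    profiles = []
    for pos in sorted(accum):
        vec = accum[pos]
        total = vec.sum()
        if total == 0:
            continue
        p = vec / total
        profiles.append(PositionProfile(position=pos, region=region_of(pos),
                                        probs=p, info=information_content(p),
                                        weighted=usage_weights is not None))
    return profiles


def write_profiles_tsv(profiles: list[PositionProfile], path) -> None:
    with open(path, "w") as fh:
        cols = ["position", "region"] + [f"p_{s if s != GAP else 'gap'}" for s in SYMBOLS]
        fh.write("\t".join(cols + ["information"]) + "\n")
        for prof in profiles:
            vals = [str(prof.position), prof.region]
            vals += [f"{x:.6g}" for x in prof.probs]
            vals.append(f"{prof.info:.6g}")
            fh.write("\t".join(vals) + "\n")
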