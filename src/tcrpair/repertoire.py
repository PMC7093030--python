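"""Paired-clonotype tables and weighted V/J gene-call resolution.

Paired-chain sequencing with short reads often cannot distinguish
closely related V (or J) genes, so aligners emit several scored
candidates per slot.  Rather than picking a winner, a clonotype's count
is split across candidate (Valpha, Jalpha, Vbeta, Jbeta) combinations in
proportion to the product of the four slot scores: a TRBV-X call scored
200 tied with TRBV-Y scored 100 on 3 clonotypes yields frequencies 2 and
1.  Splitting keeps amino-acid statistics unbiased for the V-region
stretch the reads do not cover.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .reference import AA20, strip_allele

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["cdr3_a", "v_a", "j_a", "cdr3_b", "v_b", "j_b", "count"]

_CANDIDATE = re.compile(r"^\s*([^(),\s]+)\s*(?:\(\s*([0-9.eE+-]+)\s*\))?\s*$")


@dataclass
class PairedClonotype:
    """One T-cell clone: scored V/J candidates and CDR3 per chain, plus count."""

    clonotype_id: str
    v_alpha: list[tuple[str, float]]
    j_alpha: list[tuple[str, float]]
    cdr3_alpha: str
    v_beta: list[tuple[str, float]]
    j_beta: list[tuple[str, float]]
    cdr3_beta: str
    count: float = 1.0
    epitope: str | None = None

    def candidates(self, chain: str, seg_class: str) -> list[tuple[str, float]]:
        return getattr(self, f"{seg_class.lower()}_{chain}")

    def best_gene(self, chain: str, seg_class: str) -> str:
        cands = self.candidates(chain, seg_class)
        return max(cands, key=lambda nv: (nv[1], nv[0]))[0]

    def cdr3(self, chain: str) -> str:
        return self.cdr3_alpha if chain == "alpha" else self.cdr3_beta


@dataclass
class WeightedGeneCombo:
    """One (Valpha, Jalpha, Vbeta, Jbeta) expansion of a clonotype with its weight."""

    v_alpha: str
    j_alpha: str
    v_beta: str
    j_beta: str
    weight: float
    clonotype: PairedClonotype = field(repr=False, default=None)

    @property
    def genes(self) -> tuple[str, str, str, str]:
        return (self.v_alpha, self.j_alpha, self.v_beta, self.j_beta)


def _parse_candidates(cell: str, line_no: int) -> list[tuple[str, float]]:
    out = []
    for tok in str(cell).split(","):
        m = _CANDIDATE.match(tok)
        if m is None:
            raise ValueError(f"line {line_no}: cannot parse gene candidate {tok!r}")
        out.append((m.group(1), float(m.group(2)) if m.group(2) else 1.0))
    return out


def read_paired_clonotypes(path) -> list[PairedClonotype]:
    """Parse a paired-clonotype TSV.

    Tab-separated, ``#`` comments; required columns ``cdr3_a, v_a, j_a,
    cdr3_b, v_b, j_b, count`` plus optional ``epitope`` and ``id``.
    Multi-candidate gene calls are comma-separated ``name(score)`` tokens.
    Malformed rows are skipped with a log entry.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"paired-clonotype table missing column(s): {', '.join(missing)}")
    clonotypes: list[PairedClonotype] = []
    n_rejected = 0
    valid_aa = set(AA20)
    for i, row in df.iterrows():
        line_no = i + 2
        try:
            cdr3a, cdr3b = str(row["cdr3_a"]), str(row["cdr3_b"])
            if not cdr3a or cdr3a == "nan" or not set(cdr3a) <= valid_aa:
                raise ValueError(f"line {line_no}: bad CDR3 alpha {cdr3a!r}")
            if not cdr3b or cdr3b == "nan" or not set(cdr3b) <= valid_aa:
                raise ValueError(f"line {line_no}: bad CDR3 beta {cdr3b!r}")
            count = float(row["count"])
            if count <= 0:
                raise ValueError(f"line {line_no}: non-positive count")
            clonotypes.append(PairedClonotype(
                clonotype_id=str(row.get("id", i)) if "id" in df.columns else str(i),
                v_alpha=_parse_candidates(row["v_a"], line_no),
                j_alpha=_parse_candidates(row["j_a"], line_no),
                cdr3_alpha=cdr3a,
                v_beta=_parse_candidates(row["v_b"], line_no),
                j_beta=_parse_candidates(row["j_b"], line_no),
                cdr3_beta=cdr3b,
                count=count,
                epitope=(str(row["epitope"]) if "epitope" in df.columns
                         and pd.notna(row["epitope"]) else None),
            ))
        except ValueError as exc:
            n_rejected += 1
            logger.info("skipping row: %s", exc)
    logger.info("read %d clonotypes (%d rejected)", len(clonotypes), n_rejected)
    return clonotypes


def write_paired_clonotypes(clonotypes: list[PairedClonotype], path) -> None:
    def fmt(cands):
        return ",".join(f"{n}({g:g})" for n, g in cands)

    rows = []
    for c in clonotypes:
        rows.append({
            "id": c.clonotype_id,
            "cdr3_a": c.cdr3_alpha, "v_a": fmt(c.v_alpha), "j_a": fmt(c.j_alpha),
            "cdr3_b": c.cdr3_beta, "v_b": fmt(c.v_beta), "j_b": fmt(c.j_beta),
            "count": f"{c.count:g}", "epitope": c.epitope or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def resolve_gene_calls(clonotypes: list[PairedClonotype],
                       strip_alleles: bool = True) -> list[WeightedGeneCombo]:
    """Split each clonotype's count over candidate gene combinations.

    The split is proportional to the product of the four slot scores; an
    all-zero slot falls back to a uniform split (flagged in the log).
    Total weight is conserved exactly per clonotype.
    """
    combos: list[WeightedGeneCombo] = []
    for c in clonotypes:
        slots = []
        for chain in ("alpha", "beta"):
            for seg in ("v", "j"):
                cands = c.candidates(chain, seg.upper())
                total = sum(s for _, s in cands)
                if total == 0:
                    logger.warning("clonotype %s: all-zero %s%s scores, uniform split",
                                   c.clonotype_id, seg, chain[0])
                    cands = [(n, 1.0) for n, _ in cands]
                    total = float(len(cands))
                slots.append([(strip_allele(n) if strip_alleles else n, s / total)
                              for n, s in cands])
        # aggregate duplicate names created by allele stripping
        merged_slots = []
        for slot in slots:
            agg: dict[str, float] = {}
            for n, f in slot:
                agg[n] = agg.get(n, 0.0) + f
            merged_slots.append(sorted(agg.items()))
        for va, fva in merged_slots[0]:
            for ja, fja in merged_slots[1]:
                for vb, fvb in merged_slots[2]:
                    for jb, fjb in merged_slots[3]:
                        w = c.count * fva * fja * fvb * fjb
                        if w > 0:
                            combos.append(WeightedGeneCombo(va, ja, vb, jb, w, c))
    return combos


def read_epitope_groups(path, min_group: int = 30,
                        column_map: dict[str, str] | None = None
                        ) -> dict[str, list[PairedClonotype]]:
    """Group antigen-specific paired records by epitope.

    Records missing either chain are dropped before grouping; epitopes
    with fewer than ``min_group`` surviving records are discarded.
    ``column_map`` renames foreign (e.g. VDJdb export) columns onto the
    native schema before parsing.
    """
    if column_map:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        df = df.rename(columns=column_map)
        import io
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        path = buf
    clonotypes = read_paired_clonotypes(path)
    groups: dict[str, list[PairedClonotype]] = {}
    for c in clonotypes:
        if not c.epitope:
            continue
        groups.setdefault(c.epitope, []).append(c)
    kept = {e: cs for e, cs in groups.items() if len(cs) >= min_group}
    for e, cs in sorted(groups.items()):
        logger.info("epitope %s: %d records (%s)", e, len(cs),
                    "kept" if e in kept else "dropped")
    if not kept:
        raise ValueError(f"no epitope group reaches min_group={min_group}")
    return kept
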