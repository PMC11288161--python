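"""Data model and file I/O for ranked gene lists, ranked gene sets and results.

Formats
-------
Gene list (RNK-style)
    Two-column tab-separated text ``gene<TAB>score``, optional header,
    ``#`` comment lines.  Ranks are assigned by descending score with ties
    receiving average ranks.

Ranked gene sets
    Either scored GMT — ``set_id<TAB>description<TAB>gene|score ...`` with
    the ``|score`` part optional (defaulting to 1.0) — or a long-form TSV
    with columns ``set_id, gene, score``.

Results
    TSV with columns ``set_id, n_overlap, tau, z, p_value, fdr, direction,
    p_param, weight_mode`` sorted by FDR, then p-value, then set id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "EnrichmentRecord",
    "RankedGeneList",
    "RankedGeneSet",
    "read_gene_list",
    "read_gene_sets",
    "read_results",
    "records_from_frame",
    "results_frame",
    "write_gene_list",
    "write_gene_sets",
    "write_results",
]

RESULT_COLUMNS = (
    "set_id", "n_overlap", "tau", "z", "p_value", "fdr",
    "direction", "p_param", "weight_mode",
)


def _average_ranks_desc(scores: np.ndarray) -> np.ndarray:
    """Ranks by descending score; ties get the average rank."""
    return rankdata(-np.asarray(scores, dtype=float), method="average")


def _dedupe(genes, scores, context: str):
    """Drop duplicate gene ids keeping the max |score| entry, with a warning."""
    seen: dict[str, int] = {}
    dup = False
    for idx, g in enumerate(genes):
        if g in seen:
            dup = True
            if abs(scores[idx]) > abs(scores[seen[g]]):
                seen[g] = idx
        else:
            seen[g] = idx
    if dup:
        warnings.warn(
            f"duplicate gene ids in {context}; keeping max |score|", stacklevel=3
        )
        keep = sorted(seen.values())
        genes = [genes[i] for i in keep]
        scores = [scores[i] for i in keep]
    return list(genes), np.asarray(scores, dtype=float)


@dataclass
class RankedGeneList:
    """A genome-wide ranking of genes by a score (e.g. signed -log10 FDR).

    ``ranks`` are assigned by descending score (rank 1 = highest score),
    with tied scores receiving average ranks.
    """

    genes: list[str]
    scores: np.ndarray
    ranks: np.ndarray = field(init=False)
    _index: dict[str, int] = field(init=False, repr=False)

    def __init__(self, genes, scores):
        genes = list(map(str, genes))
        scores = np.asarray(scores, dtype=float)
        if len(genes) != scores.size:
            raise ValueError("genes and scores must have equal length")
        genes, scores = _dedupe(genes, scores, "gene list")
        if len(genes) < 2:
            raise ValueError("a gene list needs at least 2 genes")
        self.genes = genes
        self.scores = scores
        self.ranks = _average_ranks_desc(scores)
        self._index = {g: i for i, g in enumerate(genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def score_of(self, gene: str) -> float:
        return float(self.scores[self._index[gene]])

    def rank_of(self, gene: str) -> float:
        return float(self.ranks[self._index[gene]])

    def subset_scores(self, genes) -> np.ndarray:
        return np.array([self.scores[self._index[g]] for g in genes])


@dataclass
class RankedGeneSet:
    """A gene set whose members carry a confidence score (e.g. binding-site
    -log10 FDR), inducing an internal rank order.

    Sets whose member scores are all equal degrade gracefully to unranked
    sets: every member receives the same average rank, which yields uniform
    set-derived weights downstream.
    """

    set_id: str
    description: str
    genes: list[str]
    scores: np.ndarray
    ranks: np.ndarray = field(init=False)

    def __init__(self, set_id, description, genes, scores):
        self.set_id = str(set_id)
        self.description = str(description)
        genes = list(map(str, genes))
        scores = np.asarray(scores, dtype=float)
        if len(genes) != scores.size:
            raise ValueError("genes and scores must have equal length")
        genes, scores = _dedupe(genes, scores, f"gene set {set_id!r}")
        self.genes = genes
        self.scores = scores
        self.ranks = _average_ranks_desc(scores) if len(genes) else np.array([])

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentRecord:
    """Per-set test outcome (one row of the result table)."""

    set_id: str
    n_overlap: int
    tau: float
    z: float
    p_value: float
    fdr: float
    direction: int
    p_param: float
    weight_mode: int
    p_method: str = "asymptotic"  # 'asymptotic' or 'permutation'; not serialized


def _data_lines(path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _parse_float(token: str):
    try:
        return float(token.replace("−", "-"))
    except ValueError:
        return None


def read_gene_list(path) -> RankedGeneList:
    """Read a two-column tab-separated gene/score file (RNK-style)."""
    genes, scores = [], []
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        score = _parse_float(fields[1])
        if score is None:
            if first:  # header row
                first = False
                continue
            raise ValueError(
                f"{path}:{lineno}: non-numeric score {fields[1]!r}"
            )
        first = False
        genes.append(fields[0].strip())
        scores.append(score)
    if len(genes) < 2:
        raise ValueError(f"{path}: a gene list needs at least 2 genes")
    return RankedGeneList(genes, scores)


def _read_gmt_scored(path) -> list[RankedGeneSet]:
    sets = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
        set_id, desc = fields[0].strip(), fields[1].strip()
        genes, scores = [], []
        for token in fields[2:]:
            token = token.strip()
            if not token:
                continue
            if "|" in token:
                gene, _, stext = token.partition("|")
                score = _parse_float(stext)
                if score is None or not gene:
                    raise ValueError(
                        f"{path}:{lineno}: malformed gene|score token {token!r}"
                    )
            else:
                gene, score = token, 1.0
            genes.append(gene)
            scores.append(score)
        sets.append(RankedGeneSet(set_id, desc, genes, scores))
    return sets


def _read_long_tsv(path) -> list[RankedGeneSet]:
    order: list[str] = []
    members: dict[str, list[tuple[str, float]]] = {}
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
        score = _parse_float(fields[2])
        if score is None:
            if first:
                first = False
                continue
            raise ValueError(f"{path}:{lineno}: non-numeric score {fields[2]!r}")
        first = False
        set_id = fields[0].strip()
        if set_id not in members:
            members[set_id] = []
            order.append(set_id)
        members[set_id].append((fields[1].strip(), score))
    return [
        RankedGeneSet(sid, "", [g for g, _ in members[sid]],
                      [s for _, s in members[sid]])
        for sid in order
    ]


def read_gene_sets(path, format: str = "gmt_scored") -> list[RankedGeneSet]:
    """Read ranked gene sets; ``format`` is ``gmt_scored`` or ``long_tsv``.

    Empty sets are dropped with a warning; duplicate (set, gene) entries keep
    the maximum score.
    """
    if format == "gmt_scored":
        sets = _read_gmt_scored(path)
    elif format == "long_tsv":
        sets = _read_long_tsv(path)
    else:
        raise ValueError(f"unknown gene-set format {format!r}")
    kept = [s for s in sets if len(s) > 0]
    if len(kept) < len(sets):
        warnings.warn(f"{path}: dropped {len(sets) - len(kept)} empty gene set(s)")
    return kept


def write_gene_sets(sets, path, format: str = "gmt_scored") -> None:
    """Write ranked gene sets in the scored-GMT or long-TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        if format == "gmt_scored":
            for s in sets:
                tokens = [f"{g}|{v:.6g}" for g, v in zip(s.genes, s.scores)]
                fh.write("\t".join([s.set_id, s.description] + tokens) + "\n")
        elif format == "long_tsv":
            fh.write("set_id\tgene\tscore\n")
            for s in sets:
                for g, v in zip(s.genes, s.scores):
                    fh.write(f"{s.set_id}\t{g}\t{v:.6g}\n")
        else:
            raise ValueError(f"unknown gene-set format {format!r}")


def write_gene_list(glist: RankedGeneList, path) -> None:
    """Write a gene list as two-column RNK-style TSV (descending score)."""
    order = np.argsort(-glist.scores, kind="mergesort")
    with open(path, "w", encoding="utf-8") as fh:
        for i in order:
            fh.write(f"{glist.genes[i]}\t{glist.scores[i]:.6g}\n")


_DIRECTION = {1: "+", 0: "0", -1: "-"}
_DIRECTION_INV = {v: k for k, v in _DIRECTION.items()}


def results_frame(records) -> pd.DataFrame:
    """Result records as a DataFrame sorted by (fdr, p_value, set_id)."""
    rows = [
        {
            "set_id": r.set_id,
            "n_overlap": r.n_overlap,
            "tau": r.tau,
            "z": r.z,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "direction": _DIRECTION[int(r.direction)],
            "p_param": r.p_param,
            "weight_mode": r.weight_mode,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    if len(df):
        df = df.sort_values(["fdr", "p_value", "set_id"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def write_results(records, path) -> None:
    """Write the result table as TSV (floats with 6 significant digits)."""
    df = results_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"set_id": str, "direction": str})
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing result columns {sorted(missing)}")
    return df


def records_from_frame(df: pd.DataFrame) -> list[EnrichmentRecord]:
    """Inverse of :func:`results_frame` (used for round-tripping)."""
    return [
        EnrichmentRecord(
            set_id=str(row.set_id), n_overlap=int(row.n_overlap),
            tau=float(row.tau), z=float(row.z), p_value=float(row.p_value),
            fdr=float(row.fdr), direction=_DIRECTION_INV[str(row.direction)],
            p_param=float(row.p_param), weight_mode=int(row.weight_mode),
        )
        for row in df.itertuples()
    ]
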