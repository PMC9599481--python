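"""Per-group lipid-protein correlation networks and over-representation tests.

Edges are Pearson correlations between every protein and every lipid within
one sample group; the dual filter keeps an edge when the correlation is
strong (|r| > r_min, p < p_corr_max) and the configured endpoint(s) are
significantly dysregulated against the reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GroupDesign, QuantTable, TableError
from .differential import DifferentialResult, bh_fdr

DEFAULT_R_MIN = 0.5
DEFAULT_P_CORR_MAX = 0.002
DEFAULT_P_DIFF_MAX = 0.05

EndpointRule = Literal["lipid", "either", "both"]


def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with df = n - 2."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def pairwise_correlations(
    table: QuantTable, design: GroupDesign, group: str
) -> pd.DataFrame:
    """Pearson r/p/q for every protein x lipid pair within one group.

    Requires an imputed table (no missing cells) and at least 5 samples in
    the group.  Zero-variance features within the group are excluded (their
    correlation is undefined).  q-values are BH within the group's full
    protein x lipid family.
    """
    samples = design.samples_in(group)
    n = len(samples)
    if n < 5:
        raise TableError(f"group {group} has {n} samples; need >=5")
    vals = table.values.loc[samples]
    if vals.isna().any().any():
        raise TableError("pairwise_correlations requires an imputed table")
    proteins = table.protein_features
    lipids = table.lipid_features
    if not proteins or not lipids:
        raise TableError("need features on both omics layers")

    p_arr = vals[proteins].to_numpy(dtype=float)
    l_arr = vals[lipids].to_numpy(dtype=float)
    p_sd = p_arr.std(axis=0, ddof=1)
    l_sd = l_arr.std(axis=0, ddof=1)
    keep_p = p_sd > 0
    keep_l = l_sd > 0
    proteins = [f for f, k in zip(proteins, keep_p) if k]
    lipids = [f for f, k in zip(lipids, keep_l) if k]
    p_arr = p_arr[:, keep_p]
    l_arr = l_arr[:, keep_l]

    pc = (p_arr - p_arr.mean(axis=0)) / p_arr.std(axis=0, ddof=1)
    lc = (l_arr - l_arr.mean(axis=0)) / l_arr.std(axis=0, ddof=1)
    r = pc.T @ lc / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    pmat = correlation_p(r, n)

    prot_idx, lip_idx = np.meshgrid(
        np.arange(len(proteins)), np.arange(len(lipids)), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "protein": np.array(proteins)[prot_idx.ravel()],
            "lipid": np.array(lipids)[lip_idx.ravel()],
            "r": r.ravel(),
            "p": pmat.ravel(),
        }
    )
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["group"] = group
    return df


@dataclass
class LipidProteinNetwork:
    """Bipartite protein-lipid network for one sample group."""

    group: str
    edges: pd.DataFrame  # columns protein, lipid, r, p, q
    lipid_classes: Mapping[str, str] = field(default_factory=dict)

    @property
    def proteins(self) -> list[str]:
        return sorted(set(self.edges["protein"]))

    @property
    def lipids(self) -> list[str]:
        return sorted(set(self.edges["lipid"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def dual_filter(
    edges: pd.DataFrame,
    diff: DifferentialResult,
    table: QuantTable,
    r_min: float = DEFAULT_R_MIN,
    p_corr_max: float = DEFAULT_P_CORR_MAX,
    p_diff_max: float = DEFAULT_P_DIFF_MAX,
    endpoint_rule: EndpointRule = "either",
) -> LipidProteinNetwork:
    """Keep edges with strong correlation and dysregulated endpoint(s).

    Edge kept iff |r| > r_min (strict), p < p_corr_max (strict) and the
    endpoint(s) designated by ``endpoint_rule`` have differential p below
    p_diff_max in the same group comparison.
    """
    if endpoint_rule not in ("lipid", "either", "both"):
        raise TableError(f"unknown endpoint rule {endpoint_rule!r}")
    group = str(edges["group"].iloc[0]) if len(edges) else None
    strong = edges[
        (edges["r"].abs() > r_min) & (edges["p"] < p_corr_max)
    ].copy()
    if group is not None and len(strong):
        dsub = diff.for_group(group)
        dysreg = set(dsub.index[dsub["p_value"] < p_diff_max])
        lip_ok = strong["lipid"].isin(dysreg)
        prot_ok = strong["protein"].isin(dysreg)
        if endpoint_rule == "lipid":
            keep = lip_ok
        elif endpoint_rule == "both":
            keep = lip_ok & prot_ok
        else:
            keep = lip_ok | prot_ok
        strong = strong[keep]
    strong = strong.sort_values(["protein", "lipid"]).reset_index(drop=True)
    classes = {
        lip: table.lipid_class_of(lip) for lip in set(strong["lipid"])
    }
    return LipidProteinNetwork(
        group=group or "", edges=strong[["protein", "lipid", "r", "p", "q"]],
        lipid_classes=classes,
    )


def hub_table(net: LipidProteinNetwork) -> pd.DataFrame:
    """Proteins ranked by number of connected lipid species.

    Descending degree, ties broken alphabetically; one column of edge
    counts per lipid class.
    """
    if net.n_edges == 0:
        return pd.DataFrame(columns=["protein", "degree"]).set_index("protein")
    edges = net.edges.copy()
    edges["lipid_class"] = edges["lipid"].map(net.lipid_classes)
    degree = edges.groupby("protein").size().rename("degree")
    by_class = (
        edges.groupby(["protein", "lipid_class"]).size().unstack(fill_value=0)
    )
    out = pd.concat([degree, by_class], axis=1)
    order = sorted(out.index, key=lambda p: (-int(out.loc[p, "degree"]), p))
    return out.loc[order].rename_axis("protein")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_network(
    net: LipidProteinNetwork,
    path: str | Path,
    fmt: Literal["sif", "graphml", "tsv"] = "sif",
) -> None:
    """Write the network as SIF, GraphML or an edge TSV (stable ordering)."""
    path = Path(path)
    edges = net.edges.sort_values(["protein", "lipid"])
    if fmt == "sif":
        lines = [
            f"{row.protein}\t{'corr_pos' if row.r >= 0 else 'corr_neg'}\t{row.lipid}"
            for row in edges.itertuples()
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "tsv":
        edges.assign(group=net.group).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        import networkx as nx

        g = nx.Graph()
        g.graph["group"] = net.group
        for prot in net.proteins:
            g.add_node(prot, layer="protein")
        for lip in net.lipids:
            g.add_node(
                lip, layer="lipid", lipid_class=net.lipid_classes.get(lip, "")
            )
        for row in edges.itertuples():
            g.add_edge(
                row.protein, row.lipid,
                r=float(row.r), p=float(row.p), q=float(row.q),
                sign="corr_pos" if row.r >= 0 else "corr_neg",
            )
        nx.write_graphml(g, path)
    else:
        raise TableError(f"unknown export format {fmt!r}")


def read_network_graphml(path: str | Path) -> LipidProteinNetwork:
    """Round-trip reader for :func:`export_network`'s GraphML output."""
    import networkx as nx

    g = nx.read_graphml(path)
    rows = []
    classes = {}
    for u, v, data in g.edges(data=True):
        if g.nodes[u].get("layer") == "protein":
            prot, lip = u, v
        else:
            prot, lip = v, u
        rows.append(
            {"protein": prot, "lipid": lip, "r": data["r"], "p": data["p"],
             "q": data["q"]}
        )
        classes[lip] = g.nodes[lip].get("lipid_class", "")
    edges = (
        pd.DataFrame(rows, columns=["protein", "lipid", "r", "p", "q"])
        .sort_values(["protein", "lipid"])
        .reset_index(drop=True)
    )
    return LipidProteinNetwork(
        group=str(g.graph.get("group", "")), edges=edges, lipid_classes=classes
    )


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise TableError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


def ora_enrichment(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    p = P(X >= overlap) with population = universe, successes = set within
    universe, draws = |query|.  BH correction across sets.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise TableError("empty universe")
    if not query:
        raise TableError("empty query")
    extra = query - universe
    if extra:
        raise TableError(f"query not contained in universe: {sorted(extra)}")
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        overlap = query & members
        k = len(overlap)
        # upper tail P(X >= k); k=0 gives exactly 1
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": len(members),
                "universe_size": len(universe),
                "query_size": len(query),
                "p": min(p, 1.0),
                "overlapping": ";".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = []
    return out.set_index("gene_set")
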