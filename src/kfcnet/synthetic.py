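"""Synthetic CTP datasets with known ground truth.

The generator emulates the statistical shape of a real herbal-formula
dataset so every pipeline stage is testable offline:

* a component table whose ADMET values make a configurable fraction
  (default ~52%, plus a handful of validated overrides) pass the all-rules
  screen;
* a bipartite component-target layer with heavy-tailed (lognormal)
  component degrees around a configurable mean (default 40) and
  preferential-attachment target degrees (implied mean ~9 at the default
  layer sizes);
* a scale-free (Barabasi-Albert) PPI layer in which disease genes are
  assortative (degree-preserving homophily swaps), heavily evidenced genes
  cluster into a module and sit on better-connected positions, and
  disease-only genes drift toward the periphery;
* publication counts with a long right tail — by default a zeta (Zipf) law
  with exponent 2, putting >50% of genes at a single publication and ~1% of
  genes above 40;
* a planted set of "key" components preferentially wired to the top weight
  decile of pathogenic genes and to that decile's PPI neighbourhood; and
* a GMT whose signal terms are enriched in the planted neighbourhood, plus
  uniform decoy terms.

The whole draw is a single pseudo-random stream determined by ``seed``:
identical seeds give byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np

from .network import ComponentRecord, PathogenicGene

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults mirror a real formula-scale dataset."""

    n_herbs: int = 7
    n_components: int = 523
    n_targets: int = 1221
    n_ppi_genes: int = 0  # extra linker proteins appearing only in the PPI layer
    n_pathogenic: int = 2973
    mean_component_degree: float = 40.0
    mean_target_degree: float = 9.4  # implied by the layer sizes; checked, not enforced
    ppi_attachment: int = 3  # Barabasi-Albert m
    pub_count_law: tuple = ("zipf", 2.0)  # or ("geometric", p)
    admet_pass_rate: float = 0.52
    n_validated: int = 9
    target_overlap_frac: float = 0.15  # fraction of pathogenic genes that are also targets
    n_planted_key_components: int = 12
    # planting strength s acts twice on each planted component: a fraction
    # min(0.9, 0.3*s) of its drawn links is redirected into the top weight
    # decile of pathogenic genes and that decile's PPI neighbourhood, and
    # 0.1*s extra links into the same pool are added on top.  The wiring is
    # therefore dominated by weight, with only a modest degree excess, so a
    # weight-blind centrality gains little from it.  Default 3.0: 90% of a
    # planted component's links are redirected and 30% extra are added.
    planting_strength: float = 3.0
    direct_planting_frac: float = 0.5  # pool links aimed at decile genes vs their nbrs
    disease_module_degree: float = 6.0  # mean intra-decile PPI edges per top-decile gene
    hub_weight_bias: float = 1.0  # exponent tying top-decile placement to PPI degree
    ppi_homophily: float = 0.9  # fraction of mixed PPI edge pairs swapped into same-layer pairs
    fresh_gene_bias: float = -3.0  # exponent placing disease-only genes toward PPI periphery (<0)
    n_terms: int = 120
    n_signal_terms: int = 30
    term_size_range: tuple[int, int] = (8, 25)
    # annotated genes beyond the network (the rest of the genome): without
    # them every query spans most of the ORA background and nothing enriches
    n_background_genes: int = 15000
    ob_missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        positive = (
            "n_herbs",
            "n_components",
            "n_targets",
            "n_pathogenic",
            "ppi_attachment",
            "n_terms",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_component_degree >= self.n_targets:
            raise ValueError(
                f"mean_component_degree ({self.mean_component_degree}) must be "
                f"smaller than n_targets ({self.n_targets})"
            )
        if not (0.0 < self.admet_pass_rate <= 1.0):
            raise ValueError("admet_pass_rate must be in (0, 1]")
        if self.n_planted_key_components < 0 or self.n_planted_key_components > self.n_components:
            raise ValueError("n_planted_key_components must be in [0, n_components]")
        law, param = self.pub_count_law
        if law not in ("zipf", "geometric"):
            raise ValueError(f"unknown pub_count_law {law!r}")
        if law == "zipf" and param <= 1.0:
            raise ValueError("zipf exponent must be > 1")
        if law == "geometric" and not (0.0 < param < 1.0):
            raise ValueError("geometric p must be in (0, 1)")


@dataclass
class SyntheticDataset:
    """One generated dataset in the same shapes the real pipeline ingests."""

    spec: SyntheticSpec
    components: list[ComponentRecord]
    ct_edges: list[tuple[str, str]]
    ppi_edges: list[tuple[str, str]]
    pathogenic: list[PathogenicGene]
    gene_sets: dict[str, set[str]]
    truth_key_components: set[str]
    signal_terms: set[str]

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Emit the delimited-text files the pipeline reads; deterministic bytes."""
        from .enrichment import write_gmt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "components": outdir / "components.tsv",
            "ct_edges": outdir / "ct_edges.tsv",
            "ppi_edges": outdir / "ppi_edges.tsv",
            "pathogenic": outdir / "pathogenic.tsv",
            "gene_sets": outdir / "gene_sets.gmt",
            "truth": outdir / "truth_key_components.txt",
        }
        with paths["components"].open("w") as fh:
            fh.write(
                "component_id\tname\therbs\tmw\tlogp\thbd\thba\trotatable_bonds"
                "\tob_percent\tgi_class\tvalidated\n"
            )
            for c in self.components:
                fh.write(
                    "\t".join(
                        [
                            c.component_id,
                            c.name,
                            ";".join(sorted(c.herbs)),
                            "" if c.mw is None else f"{c.mw:.2f}",
                            "" if c.logp is None else f"{c.logp:.2f}",
                            "" if c.hbd is None else str(c.hbd),
                            "" if c.hba is None else str(c.hba),
                            "" if c.rotatable_bonds is None else str(c.rotatable_bonds),
                            "" if c.ob_percent is None else f"{c.ob_percent:.1f}",
                            c.gi_class,
                            "true" if c.validated else "false",
                        ]
                    )
                    + "\n"
                )
        with paths["ct_edges"].open("w") as fh:
            fh.write("component_id\ttarget\n")
            for cid, t in self.ct_edges:
                fh.write(f"{cid}\t{t}\n")
        with paths["ppi_edges"].open("w") as fh:
            fh.write("protein_a\tprotein_b\n")
            for a, b in self.ppi_edges:
                fh.write(f"{a}\t{b}\n")
        with paths["pathogenic"].open("w") as fh:
            fh.write("symbol\tn_publications\n")
            for g in self.pathogenic:
                fh.write(f"{g.symbol}\t{g.n_publications}\n")
        write_gmt(self.gene_sets, paths["gene_sets"])
        with paths["truth"].open("w") as fh:
            for cid in sorted(self.truth_key_components):
                fh.write(cid + "\n")
        return paths


def _draw_pub_counts(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    name, param = law
    if name == "zipf":
        counts = rng.zipf(param, size=size)
    else:
        counts = rng.geometric(param, size=size)
    return np.minimum(counts, 1000).astype(int)


def _passing_admet(rng: np.random.Generator) -> dict:
    return {
        "mw": float(rng.uniform(150.0, 500.0)),
        "logp": float(rng.uniform(-2.0, 5.0)),
        "hbd": int(rng.integers(0, 6)),
        "hba": int(rng.integers(0, 10)),
        "rotatable_bonds": int(rng.integers(0, 10)),
        "ob_percent": float(rng.uniform(30.0, 95.0)),
        "gi_class": "high",
    }


def _violate(rng: np.random.Generator, props: dict) -> dict:
    """Break 1-3 randomly chosen screening rules so the all-rules verdict fails."""
    breakers = {
        "mw": lambda: float(rng.uniform(500.5, 900.0)),
        "logp": lambda: float(rng.uniform(5.1, 9.0)),
        "hbd": lambda: int(rng.integers(6, 11)),
        "hba": lambda: int(rng.integers(10, 16)),
        "rotatable_bonds": lambda: int(rng.integers(10, 21)),
        "ob_percent": lambda: float(rng.uniform(1.0, 29.5)),
        "gi_class": lambda: "low",
    }
    keys = sorted(breakers)
    chosen = rng.choice(keys, size=int(rng.integers(1, 4)), replace=False)
    out = dict(props)
    for key in chosen:
        out[key] = breakers[key]()
    return out


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset; fully determined by ``spec`` (including its seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    id_width = max(4, len(str(spec.n_components)))

    herbs = [f"Herb{i + 1:02d}" for i in range(spec.n_herbs)]
    comp_ids = [f"C{i + 1:0{id_width}d}" for i in range(spec.n_components)]
    targets = [f"G{i + 1:05d}" for i in range(spec.n_targets)]

    # --- ADMET table -------------------------------------------------------
    passes = rng.random(spec.n_components) < spec.admet_pass_rate
    fail_idx = np.flatnonzero(~passes)
    pool = fail_idx if len(fail_idx) >= spec.n_validated else np.arange(spec.n_components)
    validated_idx = set(
        int(i) for i in rng.choice(pool, size=min(spec.n_validated, len(pool)), replace=False)
    )
    components: list[ComponentRecord] = []
    for i, cid in enumerate(comp_ids):
        props = _passing_admet(rng)
        if passes[i]:
            if rng.random() < spec.ob_missing_rate:
                props["ob_percent"] = None  # missing OB must not eliminate the compound
        else:
            props = _violate(rng, props)
        n_h = 1 + int(rng.random() < 0.2)
        memb = frozenset(rng.choice(herbs, size=min(n_h, len(herbs)), replace=False))
        components.append(
            ComponentRecord(
                component_id=cid,
                name=f"compound-{cid}",
                herbs=memb,
                validated=(i in validated_idx),
                **props,
            )
        )
    active_idx = [i for i in range(spec.n_components) if passes[i] or i in validated_idx]
    active_ids = [comp_ids[i] for i in active_idx]
    if not active_ids:
        raise ValueError("no active components generated; raise admet_pass_rate")

    # --- component-target layer -------------------------------------------
    n_active = len(active_ids)
    raw = rng.lognormal(mean=0.0, sigma=0.9, size=n_active)
    degs = np.clip(
        np.rint(raw * spec.mean_component_degree / raw.mean()).astype(int), 1, spec.n_targets
    )
    comp_targets: dict[str, set[str]] = {cid: set() for cid in active_ids}
    target_deg = np.zeros(spec.n_targets, dtype=float)
    # every target receives one edge first, from a capacity-weighted component
    capacity = degs.astype(float)
    for j, t in enumerate(targets):
        c = int(rng.choice(n_active, p=capacity / capacity.sum()))
        comp_targets[active_ids[c]].add(t)
        target_deg[j] += 1
        capacity[c] = max(capacity[c] - 1.0, 0.25)
    # remaining slots: preferential attachment on current target degree
    t_index = {t: j for j, t in enumerate(targets)}
    for c, cid in enumerate(active_ids):
        need = int(degs[c]) - len(comp_targets[cid])
        if need <= 0:
            continue
        w = target_deg + 1.0
        for t in comp_targets[cid]:
            w[t_index[t]] = 0.0
        avail = int(np.count_nonzero(w))
        take = min(need, avail)
        picks = rng.choice(spec.n_targets, size=take, replace=False, p=w / w.sum())
        for j in picks:
            comp_targets[cid].add(targets[int(j)])
            target_deg[int(j)] += 1

    # --- pathogenic genes ---------------------------------------------------
    n_overlap = min(int(round(spec.target_overlap_frac * spec.n_pathogenic)), spec.n_targets)
    overlap = [targets[int(j)] for j in rng.choice(spec.n_targets, size=n_overlap, replace=False)]
    fresh = [f"D{i + 1:05d}" for i in range(spec.n_pathogenic - n_overlap)]
    psyms = sorted(overlap) + fresh
    pubs = _draw_pub_counts(rng, spec.pub_count_law, spec.n_pathogenic)
    pathogenic = [PathogenicGene(s, int(c)) for s, c in zip(psyms, pubs)]

    # --- PPI layer (scale free) ---------------------------------------------
    linkers = [f"X{i + 1:04d}" for i in range(spec.n_ppi_genes)]
    ppi_nodes = targets + fresh + linkers
    m = min(spec.ppi_attachment, len(ppi_nodes) - 1)
    ba = nx.barabasi_albert_graph(len(ppi_nodes), m, seed=int(rng.integers(2**31)))
    by_weight = sorted(pathogenic, key=lambda g: (-g.n_publications, g.symbol))
    decile = [g.symbol for g in by_weight[: max(1, spec.n_pathogenic // 10)]]
    # heavily evidenced disease genes tend to sit on well-connected proteins:
    # bias their placement toward high-degree positions of the scale-free
    # graph (bias 0 would decouple weight from connectivity entirely)
    ba_deg = np.array([d for _, d in sorted(ba.degree())], dtype=float)
    p_hub = ba_deg**spec.hub_weight_bias
    hub_positions = rng.choice(
        len(ppi_nodes), size=min(len(decile), len(ppi_nodes)), replace=False, p=p_hub / p_hub.sum()
    )
    taken = set(int(x) for x in hub_positions)
    rest_positions = [i for i in range(len(ppi_nodes)) if i not in taken]
    label: dict[int, str] = {}
    for pos, sym in zip(hub_positions, decile):
        label[int(pos)] = sym
    # remaining disease-only genes drift toward the periphery (predicted
    # drug targets are typically better-connected proteins); exponent 0
    # would place them uniformly
    fresh_rest = [s for s in fresh if s not in set(decile)]
    if fresh_rest and spec.fresh_gene_bias != 0.0:
        w_pos = ba_deg[rest_positions] ** spec.fresh_gene_bias
        fresh_pos = rng.choice(
            len(rest_positions),
            size=min(len(fresh_rest), len(rest_positions)),
            replace=False,
            p=w_pos / w_pos.sum(),
        )
        fresh_taken = set()
        for j, p_i in enumerate(fresh_pos):
            label[rest_positions[int(p_i)]] = fresh_rest[j]
            fresh_taken.add(rest_positions[int(p_i)])
        rest_positions = [p for p in rest_positions if p not in fresh_taken]
        rest_symbols = [s for s in ppi_nodes if s not in set(decile) and s not in set(fresh_rest)]
    else:
        rest_symbols = [s for s in ppi_nodes if s not in set(decile)]
    perm = rng.permutation(len(rest_positions))
    for j, pos in enumerate(rest_positions):
        label[pos] = rest_symbols[int(perm[j])]
    ppi = nx.Graph((label[u], label[v]) for u, v in ba.edges)

    # disease genes cluster in interaction networks: degree-preserving
    # double-edge swaps turn a fraction of pathogenic-other edge pairs into
    # pathogenic-pathogenic plus other-other, so the weighted layer is
    # assortative without touching any node's degree
    if spec.ppi_homophily > 0.0:
        pset = set(psyms)
        mixed = [
            (u, v) if u in pset else (v, u)
            for u, v in ppi.edges
            if (u in pset) != (v in pset)
        ]
        mixed = [mixed[int(i)] for i in rng.permutation(len(mixed))]
        for (p1, x), (p2, y) in zip(mixed[0::2], mixed[1::2]):
            if rng.random() >= spec.ppi_homophily:
                continue
            if p1 == p2 or x == y or ppi.has_edge(p1, p2) or ppi.has_edge(x, y):
                continue
            if not (ppi.has_edge(p1, x) and ppi.has_edge(p2, y)):
                continue
            ppi.remove_edge(p1, x)
            ppi.remove_edge(p2, y)
            ppi.add_edge(p1, p2)
            ppi.add_edge(x, y)

    # the top-decile genes additionally cluster into a PPI module (disease
    # genes co-occur in pathways); this module plus its neighbourhood is the
    # "high-weight pathogenic neighbourhood" the planted components wire into
    nd = len(decile)
    if nd > 1:
        p_mod = min(1.0, spec.disease_module_degree / (nd - 1))
        for i in range(nd):
            for j in range(i + 1, nd):
                if rng.random() < p_mod:
                    ppi.add_edge(decile[i], decile[j])
    ppi_edges = sorted((min(u, v), max(u, v)) for u, v in ppi.edges)

    # --- planting -----------------------------------------------------------
    decile_nbrs = sorted(
        {n for d in decile if d in ppi for n in ppi.neighbors(d)} - set(decile)
    )
    # planted key components are ordinary-looking in raw connectivity: they
    # are drawn from the middle band of the degree distribution, so nothing
    # short of their wiring pattern gives them away
    q_lo, q_hi = np.percentile(degs, [55.0, 90.0])
    plantable = [
        cid
        for j, (i, cid) in enumerate(zip(active_idx, active_ids))
        if passes[i] and q_lo <= degs[j] <= q_hi
    ]
    n_planted = min(spec.n_planted_key_components, len(plantable))
    planted = sorted(rng.choice(plantable, size=n_planted, replace=False)) if n_planted else []
    pub_of = dict(zip(psyms, pubs))
    decile_w = np.array([1.0 + np.log1p(pub_of[s]) for s in decile])
    redirect_frac = min(0.9, 0.3 * spec.planting_strength)
    extra_frac = 0.1 * spec.planting_strength
    # each planted component owns a round-robin slice of the decile and of
    # the decile's PPI neighbourhood (key compounds address different
    # sub-modules of the disease neighbourhood), so their coverage
    # contributions do not collapse onto each other
    n_pl = max(1, len(planted))
    slices = [decile[i::n_pl] for i in range(n_pl)]
    nbr_slices = [decile_nbrs[i::n_pl] for i in range(n_pl)]
    for idx, cid in enumerate(planted):
        d_i = len(comp_targets[cid])
        n_pool = min(int(round((redirect_frac + extra_frac) * d_i)), d_i + int(extra_frac * d_i))
        own = slices[idx]
        n_direct = min(int(round(spec.direct_planting_frac * n_pool)), len(own))
        picks = list(own[:n_direct])  # heaviest genes of this component's slice
        own_nbrs = nbr_slices[idx]
        n_nbr = min(n_pool - n_direct, len(own_nbrs))
        if n_nbr > 0:
            picks += list(rng.choice(own_nbrs, size=n_nbr, replace=False))
        # swap out ordinary targets for the redirected share of the pool links;
        # the rest of the pool links is a modest degree excess
        n_drop = min(int(round(redirect_frac * d_i)), len(comp_targets[cid] - set(picks)))
        removable = sorted(comp_targets[cid] - set(picks))
        for t in rng.choice(removable, size=n_drop, replace=False):
            comp_targets[cid].discard(str(t))
        comp_targets[cid].update(picks)

    ct_edges = sorted((cid, t) for cid, ts in comp_targets.items() for t in ts)

    # --- gene sets ----------------------------------------------------------
    background_only = [f"B{i + 1:05d}" for i in range(spec.n_background_genes)]
    universe = sorted(set(targets) | set(psyms) | set(linkers)) + background_only
    planted_targets = sorted({t for cid in planted for t in comp_targets[cid]})
    # signal terms draw from both sides of the planted neighbourhood so they
    # are enriched in the target query AND the pathogenic query (hence
    # "effective"): top-decile disease genes on one side, planted component
    # targets on the other
    pool_p = sorted(set(decile) | (set(decile_nbrs) & set(psyms)))
    pool_t = sorted(set(planted_targets) & set(targets))
    lo, hi = spec.term_size_range
    gene_sets: dict[str, set[str]] = {}
    signal_terms: set[str] = set()
    for i in range(spec.n_terms):
        term = f"TERM{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i < spec.n_signal_terms and pool_p and pool_t:
            n_p = min(int(round(0.35 * size)), len(pool_p))
            n_t = min(int(round(0.35 * size)), len(pool_t))
            members = set(rng.choice(pool_p, size=n_p, replace=False))
            members |= set(rng.choice(pool_t, size=n_t, replace=False))
            rest = min(size - len(members), len(universe))
            members |= set(rng.choice(universe, size=rest, replace=False))
            signal_terms.add(term)
        else:
            members = set(rng.choice(universe, size=min(size, len(universe)), replace=False))
        gene_sets[term] = {g.upper() for g in members}

    logger.info(
        "generate: %d components (%d active, %d planted), %d ct edges, %d ppi edges, "
        "%d pathogenic genes",
        spec.n_components,
        len(active_ids),
        len(planted),
        len(ct_edges),
        len(ppi_edges),
        spec.n_pathogenic,
    )
    return SyntheticDataset(
        spec=spec,
        components=components,
        ct_edges=ct_edges,
        ppi_edges=ppi_edges,
        pathogenic=pathogenic,
        gene_sets=gene_sets,
        truth_key_components=set(planted),
        signal_terms=signal_terms,
    )


def recovery_metrics(ranking, truth: set[str], k: int) -> dict[str, float]:
    """Precision and recall of the top-``k`` ranking prefix against ``truth``."""
    if not truth:
        raise ValueError("truth set is empty; recovery metrics undefined")
    order = ranking.order if hasattr(ranking, "order") else list(ranking)
    if k > len(order):
        raise ValueError(f"k={k} exceeds ranking length {len(order)}")
    if k <= 0:
        raise ValueError("k must be positive")
    top = set(order[:k])
    hit = len(top & truth)
    return {"precision": hit / k, "recall": hit / len(truth)}
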