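"""Cluster assignment of regulated-gene expression profiles.

The cascade mirrors a curated analysis style: expected behaviour
categories are seeded by hand-picked genes, each category's template
(the mean seed profile) is extended by correlation template matching
with the threshold fixed at the loosest value that still retrieves
every seed, leftovers are clustered by the Clustering Affinity Search
Technique (CAST) at a 0.8 Pearson threshold, CAST clusters resembling a
template group are merged back, and each final group can be split into
two subclusters at the root of an average-linkage tree.  Final labels
are the behaviour categories A-H plus X for the heterogeneous
remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)


def profile_correlations(profiles: pd.DataFrame, template: np.ndarray) -> pd.Series:
    """Pearson correlation of every gene's profile with a template.

    Genes with constant (zero-variance) profiles have undefined
    correlation and come back as NaN (the caller skips them with a
    warning); a constant template makes every correlation NaN.
    """
    x = profiles.to_numpy(dtype=float)
    t = np.asarray(template, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    xn = np.linalg.norm(xc, axis=1)
    tn = np.linalg.norm(tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ tc) / (xn * tn)
    r[(xn == 0) | (tn == 0)] = np.nan
    return pd.Series(r, index=profiles.index)


@dataclass
class BehaviourTemplate:
    """A seeded behaviour category: name, seed genes, mean seed profile."""

    name: str
    seed_genes: list[str]
    template_profile: np.ndarray

    @classmethod
    def from_seeds(cls, name: str, seed_genes, profiles: pd.DataFrame) -> "BehaviourTemplate":
        seeds = sorted(seed_genes)
        missing = [g for g in seeds if g not in profiles.index]
        if missing:
            raise ValueError(f"template {name!r}: seed genes not in profiles: {missing}")
        if len(seeds) < 2:
            raise ValueError(f"template {name!r} needs >= 2 seed genes")
        return cls(name, seeds, profiles.loc[seeds].mean(axis=0).to_numpy())


def extend_by_template(
    profiles: pd.DataFrame,
    template: BehaviourTemplate,
    mode: str = "absolute",
) -> tuple[set[str], float]:
    """Template-matching extension of a seeded group.

    The retrieval threshold ``R*`` is fixed at the largest value such
    that every seed gene is still retrieved, i.e. the minimum seed
    correlation (absolute correlation in the default ``absolute`` mode,
    signed in ``signed`` mode).  Returns the retrieved gene set and
    ``R*``.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    r = profile_correlations(profiles, template.template_profile)
    if r.isna().any():
        logger.warning(
            "%d profiles have undefined correlation to template %s; skipped",
            int(r.isna().sum()), template.name,
        )
    score = r.abs() if mode == "absolute" else r
    r_star = float(score.loc[template.seed_genes].min())
    members = set(score.index[score >= r_star - 1e-12])
    return members, r_star


def assign_templates(
    profiles: pd.DataFrame,
    seeds: dict[str, list[str]],
    mode: str = "absolute",
) -> tuple[pd.Series, dict[str, tuple[BehaviourTemplate, float]]]:
    """Run every template extension and resolve multi-matches.

    A gene retrieved by several templates is assigned to the one with
    the highest signed correlation (falling back to highest absolute
    correlation if all are negative-only matches).  Returns the partial
    assignment (gene -> label) and the fitted templates with their R*.
    """
    templates: dict[str, tuple[BehaviourTemplate, float]] = {}
    retrieved: dict[str, set[str]] = {}
    corr: dict[str, pd.Series] = {}
    for label in sorted(seeds):
        tpl = BehaviourTemplate.from_seeds(label, seeds[label], profiles)
        members, r_star = extend_by_template(profiles, tpl, mode=mode)
        templates[label] = (tpl, r_star)
        retrieved[label] = members
        corr[label] = profile_correlations(profiles, tpl.template_profile)
    assignment = {}
    for gene in profiles.index:
        candidates = [lab for lab in sorted(seeds) if gene in retrieved[lab]]
        if not candidates:
            continue
        signed = {lab: corr[lab].loc[gene] for lab in candidates}
        best = max(candidates, key=lambda lab: (signed[lab], lab))
        if signed[best] <= 0:  # only anticorrelated matches: strongest magnitude
            best = max(candidates, key=lambda lab: (abs(signed[lab]), lab))
        assignment[gene] = best
    return pd.Series(assignment, dtype=object), templates


def _similarity_matrix(profiles: pd.DataFrame) -> np.ndarray:
    x = profiles.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (xc @ xc.T) / np.outer(norms, norms)
    s[~np.isfinite(s)] = 0.0  # zero-variance profiles: no affinity
    np.fill_diagonal(s, 1.0)
    return np.clip(s, -1.0, 1.0)


def cast_cluster(profiles: pd.DataFrame, affinity_threshold: float = 0.8) -> list[list[str]]:
    """Clustering Affinity Search Technique on Pearson similarities.

    A cluster opens on the unassigned gene with the highest total
    similarity to the remaining genes, then alternates ADD passes
    (insert the highest-affinity outside gene whose mean similarity to
    the cluster is at least the threshold) and REMOVE passes (expel the
    lowest-affinity member whose mean similarity to the other members
    falls below it) until stable.  Ties break toward the
    lexicographically smallest gene id, making the partition independent
    of input order.  Singletons are allowed.
    """
    genes = sorted(profiles.index)
    profiles = profiles.loc[genes]
    s = _similarity_matrix(profiles)
    index = {g: i for i, g in enumerate(genes)}
    remaining = set(genes)
    clusters: list[list[str]] = []
    while remaining:
        rem = sorted(remaining)
        rem_idx = [index[g] for g in rem]
        totals = s[np.ix_(rem_idx, rem_idx)].sum(axis=1)
        seed = rem[int(np.lexsort((rem, -totals))[0])]
        cluster = {seed}
        changed = True
        while changed:
            changed = False
            # ADD pass
            while True:
                outside = sorted(remaining - cluster)
                if not outside:
                    break
                cl_idx = [index[g] for g in sorted(cluster)]
                aff = {g: s[index[g], cl_idx].sum() for g in outside}
                ok = [g for g in outside if aff[g] >= affinity_threshold * len(cluster)]
                if not ok:
                    break
                best = min(ok, key=lambda g: (-aff[g], g))
                cluster.add(best)
                changed = True
            # REMOVE pass
            while len(cluster) > 1:
                members = sorted(cluster)
                aff = {
                    g: sum(s[index[g], index[h]] for h in members if h != g)
                    for g in members
                }
                low = [
                    g for g in members
                    if aff[g] < affinity_threshold * (len(cluster) - 1)
                ]
                if not low:
                    break
                worst = min(low, key=lambda g: (aff[g], g))
                cluster.remove(worst)
                changed = True
        clusters.append(sorted(cluster))
        remaining -= cluster
    return clusters


def merge_matching_clusters(
    cast_clusters: list[list[str]],
    templates: dict[str, tuple[BehaviourTemplate, float]],
    profiles: pd.DataFrame,
    mode: str = "absolute",
) -> tuple[dict[str, list[str]], list[list[str]]]:
    """Fold CAST clusters back into template groups they resemble.

    A CAST cluster merges into a template group when the correlation of
    its mean profile to the group's template exceeds that group's
    chosen R* (absolute or signed per ``mode``); among several, the
    highest correlation wins.  Unmatched clusters are returned as novel.
    """
    merged: dict[str, list[str]] = {label: [] for label in templates}
    novel: list[list[str]] = []
    for cluster in cast_clusters:
        mean_profile = profiles.loc[cluster].mean(axis=0).to_numpy()
        best_label, best_score = None, -np.inf
        for label, (tpl, r_star) in sorted(templates.items()):
            r = profile_correlations(
                pd.DataFrame([mean_profile]), tpl.template_profile
            ).iloc[0]
            if np.isnan(r):
                continue
            score = abs(r) if mode == "absolute" else r
            if score > r_star and score > best_score:
                best_label, best_score = label, score
        if best_label is None:
            novel.append(cluster)
        else:
            merged[best_label].extend(cluster)
    return merged, novel


def hierarchical_split(profiles: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split a group in two at the root of an average-linkage tree.

    Euclidean distances, average linkage; the cut keeps the root's two
    children (the two most external nodes).  Groups of one come back
    unsplit with a warning.  The subcluster containing the
    lexicographically smallest gene is returned first.
    """
    genes = sorted(profiles.index)
    if len(genes) < 2:
        logger.warning("group of %d gene(s) returned unsplit", len(genes))
        return genes, []
    z = linkage(profiles.loc[genes].to_numpy(dtype=float), method="average",
                metric="euclidean")
    labels = fcluster(z, t=2, criterion="maxclust")
    first_lab = labels[0]
    a = [g for g, l in zip(genes, labels) if l == first_lab]
    b = [g for g, l in zip(genes, labels) if l != first_lab]
    return a, b


def assign_clusters(
    profiles: pd.DataFrame,
    seeds: dict[str, list[str]],
    affinity_threshold: float = 0.8,
    mode: str = "absolute",
    split: bool = True,
) -> pd.DataFrame:
    """Full cascade: templates -> CAST -> merge -> hierarchical split.

    Returns a DataFrame indexed by gene with columns ``label`` (A-H or
    X), ``stage`` (template / cast / merged), and ``subcluster`` (1 or
    2 within the label's average-linkage split, 0 when unsplit).  The
    labels partition the input gene set.
    """
    template_assign, templates = assign_templates(profiles, seeds, mode=mode)
    label = pd.Series("X", index=profiles.index, dtype=object)
    stage = pd.Series("cast", index=profiles.index, dtype=object)
    label.loc[template_assign.index] = template_assign
    stage.loc[template_assign.index] = "template"
    unassigned = profiles.index.difference(template_assign.index)
    if len(unassigned) > 0:
        clusters = cast_cluster(profiles.loc[unassigned], affinity_threshold)
        merged, novel = merge_matching_clusters(clusters, templates, profiles, mode=mode)
        for lab, genes in merged.items():
            if genes:
                label.loc[genes] = lab
                stage.loc[genes] = "merged"
        for cluster in novel:
            label.loc[cluster] = "X"
    out = pd.DataFrame({"label": label, "stage": stage})
    out["subcluster"] = 0
    if split:
        for lab in sorted(out["label"].unique()):
            genes = out.index[out["label"] == lab]
            if len(genes) < 2:
                continue
            a, b = hierarchical_split(profiles.loc[genes])
            out.loc[a, "subcluster"] = 1
            out.loc[b, "subcluster"] = 2
    out.index.name = "gene_id"
    return out.sort_index()
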