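"""Promoter motif analysis.

Implements the promoter arm of the target-mapping pipeline:

* strand-aware extraction of upstream (promoter) sequences from a gene
  coordinate table and a genome FASTA;
* greedy non-overlapping scanning of degenerate IUPAC consensi
  (the CreA/CRE1 site ``SYGGRG`` being the motivating case);
* dyad (paired-motif) counting with a bounded spacer, the proxy for the
  functionally required double binding sites;
* per-cluster enrichment of site densities against the genome-wide
  average, tested with Welch's t;
* de novo over-represented word discovery with random same-size control
  gene sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .iupac import DyadSpec, IUPACPattern, pattern_to_regex

logger = logging.getLogger(__name__)

CRE1_SITE = IUPACPattern("SYGGRG")
CRE1_SITE_RC = IUPACPattern("CYCCRS")


# ---------------------------------------------------------------------------
# promoter retrieval
# ---------------------------------------------------------------------------

class MissingContigError(KeyError):
    pass


def retrieve_promoters(
    genes: pd.DataFrame,
    genome,
    length: int = 1000,
) -> dict[str, str]:
    """Extract upstream sequences (default the -1000..-1 window).

    Parameters
    ----------
    genes : DataFrame with columns ``gene_id, contig, start, end, strand``
        (1-based inclusive coordinates, strand ``+``/``-``).
    genome : mapping contig -> sequence string, or a ``pyfaidx.Fasta``.
    length : number of upstream bases to take.

    For a plus-strand gene the promoter is the ``length`` bases
    immediately 5' of ``start``; for a minus-strand gene it is the
    reverse complement of the ``length`` bases immediately 3' of
    ``end``.  Windows running off a contig edge are truncated with a
    warning.  Upstream ORFs are not masked or clipped.
    """
    from .iupac import reverse_complement

    promoters: dict[str, str] = {}
    for row in genes.itertuples(index=False):
        try:
            contig = genome[row.contig]
        except KeyError:
            raise MissingContigError(
                f"gene {row.gene_id!r}: contig {row.contig!r} not in genome"
            ) from None
        seq = str(contig[:]) if hasattr(contig, "__getitem__") and not isinstance(contig, str) else str(contig)
        if row.strand == "+":
            hi = int(row.start) - 1          # 0-based exclusive end
            lo = max(0, hi - length)
            window = seq[lo:hi]
        elif row.strand == "-":
            lo = int(row.end)                # 0-based inclusive start
            hi = min(len(seq), lo + length)
            window = reverse_complement(seq[lo:hi])
        else:
            raise ValueError(f"gene {row.gene_id!r}: strand must be '+' or '-'")
        if len(window) < length:
            logger.warning(
                "promoter of %s truncated to %d bp at contig edge", row.gene_id, len(window)
            )
        promoters[row.gene_id] = window.upper()
    return promoters


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def scan_pattern(pattern: IUPACPattern | str, sequence: str) -> list[int]:
    """Greedy non-overlapping matches of a degenerate pattern.

    Positions are scanned left to right; a match at position ``i``
    consumes ``len(pattern)`` bases and scanning resumes immediately
    after it (the "prevent overlapping matches" behaviour).  Because
    every match has the same length, this greedy rule yields a
    maximum-cardinality set of non-overlapping occurrences.  Only the
    given strand is scanned; reverse-strand sites are obtained by
    scanning the reverse-complement pattern explicitly.

    Returns 0-based start positions.
    """
    if not isinstance(pattern, IUPACPattern):
        pattern = IUPACPattern(pattern)
    rx = pattern_to_regex(pattern.pattern)
    return [m.start() for m in rx.finditer(sequence.upper())]


def count_pattern(pattern: IUPACPattern | str, sequence: str) -> int:
    return len(scan_pattern(pattern, sequence))


def scan_dyad(dyad: DyadSpec, sequence: str, anchor: str = "gap") -> int:
    """Count qualifying ordered motif pairs in a sequence.

    Match sets for the two component patterns come from
    :func:`scan_pattern` independently.  A pair ``(i, j)`` qualifies
    when the second match starts at or after the end of the first
    (``j >= i + len(first)``, so the two sites never overlap) and the
    spacer is within bounds.  With ``anchor='gap'`` (default) the
    constraint is ``0 <= j - (i + len(first)) <= max_gap``; with
    ``anchor='start'`` it is ``j - i <= max_gap``.  Every qualifying
    combination counts once.
    """
    if anchor not in ("gap", "start"):
        raise ValueError("anchor must be 'gap' or 'start'")
    first_pos = scan_pattern(dyad.first, sequence)
    second_pos = scan_pattern(dyad.second, sequence)
    l1 = len(dyad.first)
    count = 0
    for i in first_pos:
        for j in second_pos:
            if j < i + l1:
                continue
            gap = j - (i + l1) if anchor == "gap" else j - i
            if gap <= dyad.max_gap:
                count += 1
    return count


def count_sites_per_gene(
    promoters: dict[str, str],
    motifs: dict[str, IUPACPattern | DyadSpec],
    anchor: str = "gap",
) -> pd.DataFrame:
    """Per-gene site counts for a set of motifs/dyads.

    Returns a DataFrame indexed by gene with one integer column per
    motif name.
    """
    records = {}
    for name, motif in motifs.items():
        if isinstance(motif, DyadSpec):
            records[name] = {g: scan_dyad(motif, s, anchor=anchor) for g, s in promoters.items()}
        else:
            records[name] = {g: count_pattern(motif, s) for g, s in promoters.items()}
    out = pd.DataFrame(records)
    out.index.name = "gene_id"
    return out.sort_index()


def mean_sites_per_gene(counts: pd.Series) -> float:
    """Genome- or cluster-wide average number of sites per gene."""
    return float(np.asarray(counts, dtype=float).mean())


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class MotifEnrichment:
    """Cluster-vs-genome site-density comparison for one motif."""

    cluster: str
    motif: str
    cluster_mean: float
    genome_mean: float
    enrichment_pct: float
    p: float
    n_cluster: int
    n_genome: int

    @property
    def stars(self) -> str:
        if self.p < 0.05:
            return "**"
        if self.p < 0.1:
            return "*"
        return ""


def cluster_enrichment(
    counts: pd.Series,
    cluster_genes,
    genome_genes=None,
    cluster: str = "",
    motif: str = "",
    include_cluster_in_background: bool = True,
) -> MotifEnrichment:
    """Site-density enrichment of a gene cluster over the genome mean.

    The cluster's mean sites/gene is normalised to the genome-wide mean
    and reported as a percent deviation, ``(cluster/genome - 1) * 100``.
    Significance is a two-sided Welch (unequal-variance) t-test of the
    cluster counts against the genome counts.
    """
    if genome_genes is None:
        genome_genes = counts.index
    cluster_genes = [g for g in cluster_genes]
    if len(cluster_genes) < 2:
        raise ValueError("cluster must contain at least 2 genes for the t-test")
    missing = set(cluster_genes) - set(counts.index)
    if missing:
        raise ValueError(f"cluster genes missing from counts: {sorted(missing)[:5]}")
    background = list(genome_genes)
    if not include_cluster_in_background:
        background = [g for g in background if g not in set(cluster_genes)]
    x = counts.loc[cluster_genes].to_numpy(dtype=float)
    y = counts.loc[background].to_numpy(dtype=float)
    genome_mean = float(y.mean())
    cluster_mean = float(x.mean())
    if genome_mean == 0:
        raise ValueError("genome mean site count is zero; enrichment undefined")
    pct = (cluster_mean / genome_mean - 1.0) * 100.0
    if np.allclose(x.var(), 0) and np.allclose(y.var(), 0) and np.isclose(cluster_mean, y.mean()):
        p = 1.0
    else:
        p = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
        if math.isnan(p):
            p = 1.0
    return MotifEnrichment(
        cluster=cluster, motif=motif,
        cluster_mean=cluster_mean, genome_mean=genome_mean,
        enrichment_pct=pct, p=p,
        n_cluster=len(x), n_genome=len(y),
    )


def enrichment_table(
    counts: pd.DataFrame,
    assignments: pd.Series,
    include_cluster_in_background: bool = True,
) -> pd.DataFrame:
    """Cluster x motif enrichment table.

    ``assignments`` maps gene -> cluster label.  The first row carries
    the genome-wide mean sites/gene for each motif; cluster rows carry
    the percent enrichment annotated with ``*`` (p < 0.1) or ``**``
    (p < 0.05) from the Welch test.  A long-format numeric table is
    attached as ``.attrs['records']``.
    """
    labels = sorted(assignments.dropna().unique())
    rows: dict[str, dict[str, str]] = {"genome_mean": {}}
    records = []
    for motif in counts.columns:
        rows["genome_mean"][motif] = f"{counts[motif].mean():.2f}"
    for label in labels:
        genes = assignments.index[assignments == label]
        row = {}
        for motif in counts.columns:
            enr = cluster_enrichment(
                counts[motif], genes, cluster=str(label), motif=motif,
                include_cluster_in_background=include_cluster_in_background,
            )
            row[motif] = f"{enr.enrichment_pct:+.0f}%{enr.stars}"
            records.append(enr)
        rows[str(label)] = row
    table = pd.DataFrame(rows).T
    table.index.name = "cluster"
    table.attrs["records"] = pd.DataFrame(
        [
            {
                "cluster": r.cluster, "motif": r.motif,
                "cluster_mean": r.cluster_mean, "genome_mean": r.genome_mean,
                "enrichment_pct": r.enrichment_pct, "p": r.p,
                "n_cluster": r.n_cluster, "n_genome": r.n_genome,
            }
            for r in records
        ]
    )
    return table


# ---------------------------------------------------------------------------
# de novo discovery
# ---------------------------------------------------------------------------

def _word_presence(promoters: dict[str, str], length: int) -> dict[str, set[str]]:
    """word -> set of genes whose promoter contains it at least once."""
    presence: dict[str, set[str]] = {}
    for gene, seq in promoters.items():
        seen = set()
        for i in range(len(seq) - length + 1):
            w = seq[i : i + length]
            if "N" in w:
                continue
            seen.add(w)
        for w in seen:
            presence.setdefault(w, set()).add(gene)
    return presence


def _word_scores(
    genes: set[str],
    presence: dict[str, set[str]],
    n_universe: int,
    length: int,
) -> dict[str, float]:
    """Significance index per word: -log10 of the Bonferroni-scaled
    binomial upper-tail probability of the word's presence count in the
    gene set, under the genome-wide per-promoter presence probability.
    """
    n = len(genes)
    n_words = 4 ** length
    scores: dict[str, float] = {}
    for word, carriers in presence.items():
        if len(word) != length:
            continue
        k = len(genes & carriers)
        if k == 0:
            continue
        # clip the background presence probability away from 0/1
        p_bg = min(max(len(carriers) / n_universe, 0.5 / n_universe), 1 - 0.5 / n_universe)
        tail = sps.binom.sf(k - 1, n, p_bg)
        ev = tail * n_words
        scores[word] = float(-np.log10(max(ev, 1e-300)))
    return scores


@dataclass
class DiscoveredMotif:
    word: str
    length: int
    k: int
    n: int
    score: float
    threshold: float


def discover_motifs(
    cluster_genes,
    promoters: dict[str, str],
    word_lengths=(5, 6, 7, 8),
    n_controls: int = 3,
    score_margin: float = 0.5,
    rng=None,
) -> pd.DataFrame:
    """De novo over-represented oligonucleotides in a cluster's promoters.

    For each word length, every word's significance index (see
    :func:`_word_scores`) in the cluster is compared against the highest
    index obtained in ``n_controls`` random gene sets of the same size
    drawn from the full promoter universe; a word is accepted when its
    index exceeds that control maximum plus ``score_margin``.

    Returns a DataFrame of accepted words (word, length, k, n, score,
    threshold), sorted by descending score.
    """
    rng = np.random.default_rng(rng)
    cluster_genes = set(cluster_genes)
    universe = sorted(promoters)
    if not cluster_genes:
        raise ValueError("cluster is empty")
    if len(cluster_genes) > len(universe):
        raise ValueError("cluster larger than promoter universe")
    if not cluster_genes <= set(universe):
        raise ValueError("cluster genes missing from promoter set")
    n_universe = len(universe)
    accepted = []
    for length in word_lengths:
        presence = _word_presence(promoters, length)
        cluster_scores = _word_scores(cluster_genes, presence, n_universe, length)
        control_max = 0.0
        for _ in range(n_controls):
            ctrl = set(rng.choice(universe, size=len(cluster_genes), replace=False))
            ctrl_scores = _word_scores(ctrl, presence, n_universe, length)
            if ctrl_scores:
                control_max = max(control_max, max(ctrl_scores.values()))
        threshold = control_max + score_margin
        for word, score in cluster_scores.items():
            if score > threshold:
                k = len(cluster_genes & presence[word])
                accepted.append(
                    DiscoveredMotif(word, length, k, len(cluster_genes), score, threshold)
                )
    out = pd.DataFrame([vars(m) for m in accepted],
                       columns=["word", "length", "k", "n", "score", "threshold"])
    return out.sort_values("score", ascending=False, ignore_index=True)
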