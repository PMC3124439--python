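"""Synthetic two-colour microarray experiments with planted ground truth.

The generator emulates the structure of a chemostat knockout study of a
carbon-catabolite regulator: two strains (wild type and regulator
deletion) at two dilution rates (0.07 h^-1 repressing, 0.025 h^-1
derepressing), compared pairwise in four hybridised contrasts, each with
two dye-swap biological replicates on a multi-probe-per-transcript
array.  Everything downstream of the scanner is produced here — raw
GPR-like result tables, the probe->transcript map, promoter FASTA and
gene->category annotations — together with a record of the planted
truth (regulated genes, cluster memberships, planted motif counts) so
every pipeline stage can be tested without any external download.

Intensity model: each spot has a log-normal common intensity (channel
geometric mean ``2^A`` with ``A ~ N(10, 1.5)``) and a log-ratio
``M = orientation * true_log2 + N(0, noise_sd)``; the two channels are
``2^(A ± M/2)``.  Dye-swapped replicates exchange channel roles, so the
raw ratio sign flips between replicates of a comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .iupac import IUPAC_CODES, DyadSpec, IUPACPattern

FLAG_OK = 0
FLAG_NOT_FOUND = -50
FLAG_BAD = -100

CONDITIONS = ("wt_high", "wt_low", "dcre1_high", "dcre1_low")

#: the four pairwise contrasts (numerator, denominator)
COMPARISONS: dict[str, tuple[str, str]] = {
    "c1": ("wt_low", "wt_high"),        # growth-rate effect, wild type
    "c2": ("dcre1_low", "dcre1_high"),  # growth-rate effect, knockout
    "c3": ("dcre1_high", "wt_high"),    # regulator effect, high growth rate
    "c4": ("dcre1_low", "wt_low"),      # regulator effect, low growth rate
}

CLUSTER_LABELS = tuple("ABCDEFGH") + ("X",)

#: behaviour-category centroids over (c1, c2, c3, c4), in log2 units.
#: A/B respond to growth rate only; C-H involve the regulator (C: up in
#: knockout at both rates, D/F: down in knockout at low/high rate,
#: E: up in knockout at high rate, G/H: regulator counteracting an
#: induction at high/low rate); X is a heterogeneous leftover profile.
CLUSTER_CENTROIDS: dict[str, tuple[float, float, float, float]] = {
    "A": (1, 1, 0, 0),
    "B": (-1, -1, 0, 0),
    "C": (0, 0, 1, 1),
    "D": (0, 0, 0, -1),
    "E": (0, 0, 1, 0),
    "F": (0, 0, -1, 0),
    "G": (-1, 0, 1, 0),
    "H": (0, -1, 0, 1),
    "X": (1, -1, 1, -1),
}

#: published per-cluster gene counts used as the default planted sizes
DEFAULT_CLUSTER_SIZES: dict[str, int] = {
    "A": 19, "B": 24, "C": 16, "D": 36, "E": 50,
    "F": 36, "G": 26, "H": 26, "X": 17,
}


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class PlantedMotif:
    motif: IUPACPattern | DyadSpec
    cluster: str
    rate: float  # expected planted instances per target-cluster gene


@dataclass
class SimulationConfig:
    n_genes: int
    probes_per_gene: int = 7
    n_comparisons: int = 4
    dye_swap_replicates: int = 2
    true_log2: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.2
    bio_sd: float = 0.25  # per-gene biological replicate effect (log2)
    flag_rate: float = 0.02
    bad_flag_rate: float = 0.01
    saturation_rate: float = 0.005
    promoter_length: int = 1000
    background_gc: float = 0.5
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    cluster_membership: dict[str, str] = field(default_factory=dict)
    offstrand_probe_rate: float = 0.1
    saturation_ceiling: float = 65535.0
    regulated_threshold: float = 2.0
    annotated_fraction: float = 4977 / 9129
    planted_category: str = "FC01"
    planted_category_cluster: str = "E"
    planted_category_rate: float = 0.8
    n_categories: int = 20
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.probes_per_gene < 1:
            raise ConfigError("probes_per_gene must be >= 1")
        if self.n_comparisons != 4:
            raise ConfigError("n_comparisons is fixed at 4")
        if self.dye_swap_replicates < 2:
            raise ConfigError("dye_swap_replicates must be >= 2")
        for name in ("flag_rate", "bad_flag_rate", "saturation_rate",
                     "background_gc", "annotated_fraction", "offstrand_probe_rate",
                     "planted_category_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.bio_sd < 0:
            raise ConfigError("bio_sd must be >= 0")
        for pm in self.planted_motifs:
            span = pm.motif.span if isinstance(pm.motif, DyadSpec) else len(pm.motif)
            if span > self.promoter_length:
                raise ConfigError("promoter_length shorter than a planted motif span")
            if pm.rate < 0:
                raise ConfigError("planted motif rate must be >= 0")

    @property
    def genes(self) -> list[str]:
        return [f"g{i:05d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated experiment."""

    regulated_genes: dict[str, set[str]]
    cluster_membership: dict[str, str]
    true_log2: dict[str, dict[str, float]]
    planted_motif_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_category: str | None = None
    planted_category_cluster: str | None = None

    @property
    def regulated_union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.regulated_genes.values():
            out |= genes
        return out

    def to_json(self, path) -> None:
        payload = {
            "regulated_genes": {c: sorted(g) for c, g in self.regulated_genes.items()},
            "cluster_membership": self.cluster_membership,
            "true_log2": self.true_log2,
            "planted_motif_counts": self.planted_motif_counts,
            "planted_category": self.planted_category,
            "planted_category_cluster": self.planted_category_cluster,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def planted_cluster_config(
    cluster_sizes: dict[str, int] | None = None,
    n_genes: int = 1000,
    magnitude: float = 3.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """Configuration with regulated genes planted from the behaviour
    centroids.

    ``cluster_sizes`` maps labels A..H, X to gene counts (default: the
    published cluster sizes, 250 regulated genes in total); remaining
    genes are unregulated.  Membership is assigned to a random
    (seed-determined) subset of gene ids.  Centroids are scaled to
    ``magnitude`` so every regulated gene has at least one comparison
    with ``|true log2| = magnitude``.
    """
    sizes = dict(DEFAULT_CLUSTER_SIZES if cluster_sizes is None else cluster_sizes)
    total = sum(sizes.values())
    if total > n_genes:
        raise ConfigError("n_genes smaller than the sum of cluster sizes")
    cfg = SimulationConfig(n_genes=n_genes, noise_sd=noise_sd, rng_seed=seed, **kwargs)
    rng = np.random.default_rng([seed, 101])
    genes = cfg.genes
    picked = rng.choice(len(genes), size=total, replace=False)
    membership: dict[str, str] = {}
    true_log2: dict[str, dict[str, float]] = {c: {} for c in COMPARISONS}
    pos = 0
    for label in CLUSTER_LABELS:
        for _ in range(sizes.get(label, 0)):
            g = genes[picked[pos]]
            pos += 1
            membership[g] = label
            for ci, comp in enumerate(COMPARISONS):
                v = CLUSTER_CENTROIDS[label][ci] * magnitude
                if v != 0:
                    true_log2[comp][g] = float(v)
    cfg.cluster_membership = membership
    cfg.true_log2 = true_log2
    return cfg


# ---------------------------------------------------------------------------
# raw array tables
# ---------------------------------------------------------------------------

def _make_probe_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for g in config.genes:
        for k in range(1, config.probes_per_gene + 1):
            rows.append(
                {
                    "probe_id": f"{g}_p{k}",
                    "transcript_id": g,
                    "in_coding_on_matching_strand":
                        bool(rng.random() >= config.offstrand_probe_rate),
                }
            )
    return pd.DataFrame(rows)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[dict[tuple[str, int], pd.DataFrame], pd.DataFrame, SyntheticTruth]:
    """Simulate raw result tables for 4 comparisons x 2 dye-swap replicates.

    Returns ``(tables, probe_map, truth)`` where ``tables`` maps
    ``(comparison_id, replicate)`` to a GPR-like DataFrame with columns
    ``probe_id, transcript_id, block, row, col, F635_mean, F532_mean,
    flag``.  Replicate 1 carries the numerator condition in channel 1
    (F635); replicate 2 is dye-swapped, so its raw log-ratio sign is
    inverted.  A ``flag_rate`` fraction of spots is flagged "not found"
    with intensities drawn well below the unflagged distribution, and a
    ``saturation_rate`` fraction is pushed into the scanner ceiling.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 11])
    probe_map = _make_probe_map(config, rng)
    n_spots = len(probe_map)
    true = {
        comp: np.array([config.true_log2.get(comp, {}).get(g, 0.0) for g in probe_map["transcript_id"]])
        for comp in COMPARISONS
    }
    tables: dict[tuple[str, int], pd.DataFrame] = {}
    n_rows = max(1, int(np.ceil(np.sqrt(n_spots))))
    grid_row = np.arange(n_spots) // n_rows + 1
    grid_col = np.arange(n_spots) % n_rows + 1
    for comp in COMPARISONS:
        for rep in range(1, config.dye_swap_replicates + 1):
            orientation = 1.0 if rep % 2 == 1 else -1.0
            a = rng.normal(10.0, 1.5, size=n_spots)
            ratio = true[comp]
            if config.bio_sd > 0:
                # biological effect: shared by all probes of a gene in
                # this replicate, independent between replicates
                gene_effect = rng.normal(0.0, config.bio_sd, size=config.n_genes)
                ratio = ratio + np.repeat(gene_effect, config.probes_per_gene)
            m = orientation * ratio
            if config.noise_sd > 0:
                m = m + rng.normal(0.0, config.noise_sd, size=n_spots)
            sat = rng.random(n_spots) < config.saturation_rate
            a[sat] = np.log2(config.saturation_ceiling) + 2.0
            ch1 = np.minimum(2 ** (a + m / 2.0), config.saturation_ceiling)
            ch2 = np.minimum(2 ** (a - m / 2.0), config.saturation_ceiling)
            u = rng.random(n_spots)
            flag = np.full(n_spots, FLAG_OK, dtype=int)
            nf = u < config.flag_rate
            bad = (~nf) & (u < config.flag_rate + config.bad_flag_rate)
            flag[nf] = FLAG_NOT_FOUND
            flag[bad] = FLAG_BAD
            low = 2 ** rng.normal(6.0, 0.5, size=(nf.sum(), 2))
            ch1[nf] = low[:, 0]
            ch2[nf] = low[:, 1]
            tables[(comp, rep)] = pd.DataFrame(
                {
                    "probe_id": probe_map["probe_id"],
                    "transcript_id": probe_map["transcript_id"],
                    "block": 1,
                    "row": grid_row,
                    "col": grid_col,
                    "F635_mean": ch1,
                    "F532_mean": ch2,
                    "flag": flag,
                }
            )
    truth = SyntheticTruth(
        regulated_genes={
            comp: {g for g, v in config.true_log2.get(comp, {}).items()
                   if abs(v) > config.regulated_threshold}
            for comp in COMPARISONS
        },
        cluster_membership=dict(config.cluster_membership),
        true_log2={c: dict(v) for c, v in config.true_log2.items()},
        planted_category=config.planted_category,
        planted_category_cluster=config.planted_category_cluster,
    )
    return tables, probe_map, truth


def design_table(config: SimulationConfig) -> pd.DataFrame:
    """Hybridisation design: comparison, conditions, replicate, orientation."""
    rows = []
    for comp, (num, den) in COMPARISONS.items():
        for rep in range(1, config.dye_swap_replicates + 1):
            rows.append(
                {
                    "comparison_id": comp,
                    "numerator": num,
                    "denominator": den,
                    "replicate": rep,
                    "orientation": "forward" if rep % 2 == 1 else "swapped",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _realize(pattern: IUPACPattern, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC_CODES[c][rng.integers(len(IUPAC_CODES[c]))] for c in pattern.pattern
    )


def simulate_promoters(
    config: SimulationConfig,
    truth: SyntheticTruth,
) -> dict[str, str]:
    """I.i.d. background promoters with motif instances planted in
    target-cluster genes.

    Background bases are drawn independently with the configured GC
    fraction.  For each planted motif the per-gene instance count is the
    integer part of the rate plus a Bernoulli draw on the fraction;
    instances are concrete realisations of the degenerate pattern placed
    at uniformly random non-overlapping positions.  Planted counts (but
    not incidental background matches) are recorded in
    ``truth.planted_motif_counts``.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 23])
    gc = config.background_gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    for g in config.genes:
        seq = rng.choice(4, size=config.promoter_length, p=probs)
        chars = bases[seq].tolist()
        occupied: list[tuple[int, int]] = []
        label = truth.cluster_membership.get(g)
        for pm in config.planted_motifs:
            if label != pm.cluster:
                continue
            n_inst = int(pm.rate) + int(rng.random() < pm.rate - int(pm.rate))
            planted = 0
            for _ in range(n_inst):
                if isinstance(pm.motif, DyadSpec):
                    gap = int(rng.integers(0, pm.motif.max_gap + 1))
                    inst = (
                        _realize(pm.motif.first, rng)
                        + "".join(bases[rng.choice(4, size=gap, p=probs)])
                        + _realize(pm.motif.second, rng)
                    )
                else:
                    inst = _realize(pm.motif, rng)
                span = len(inst)
                for _attempt in range(200):
                    start = int(rng.integers(0, config.promoter_length - span + 1))
                    if all(start + span <= lo or start >= hi for lo, hi in occupied):
                        chars[start : start + span] = list(inst)
                        occupied.append((start, start + span))
                        planted += 1
                        break
            if planted:
                counts.setdefault(g, {})
                key = str(pm.motif)
                counts[g][key] = counts[g].get(key, 0) + planted
        promoters[g] = "".join(chars)
    truth.planted_motif_counts = counts
    return promoters


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    config: SimulationConfig,
    truth: SyntheticTruth,
    namespace: str = "funcat",
) -> pd.DataFrame:
    """Gene -> category annotation table with one planted enrichment.

    A fraction ``annotated_fraction`` of genes carries 1-3 uniformly
    chosen categories; genes of ``planted_category_cluster`` (if
    annotated) additionally carry ``planted_category`` with probability
    ``planted_category_rate``, creating a known over-representation for
    the hypergeometric stage to find.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 31])
    genes = config.genes
    n_annot = int(round(config.annotated_fraction * config.n_genes))
    annotated = set(np.array(genes)[rng.choice(config.n_genes, size=n_annot, replace=False)])
    categories = [f"FC{i:02d}" for i in range(1, config.n_categories + 1)]
    background = [c for c in categories if c != config.planted_category]
    rows = []
    for g in genes:
        if g not in annotated:
            continue
        cats = set(rng.choice(background, size=int(rng.integers(1, 4)), replace=False))
        if (
            truth.cluster_membership.get(g) == config.planted_category_cluster
            and rng.random() < config.planted_category_rate
        ):
            cats.add(config.planted_category)
        for c in sorted(cats):
            rows.append({"gene_id": g, "category_id": c, "namespace": namespace})
    return pd.DataFrame(rows, columns=["gene_id", "category_id", "namespace"])


# ---------------------------------------------------------------------------
# plain-text writers
# ---------------------------------------------------------------------------

def write_gpr(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_probe_map(probe_map: pd.DataFrame, path) -> None:
    probe_map.to_csv(path, sep="\t", index=False)


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
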