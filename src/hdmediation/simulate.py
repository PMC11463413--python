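"""Synthetic multiparent-population data with controllable genetic architecture.

The generator emulates the two study designs end to end: an outbred discovery
population whose chromosomes are random founder mosaics (Markov founder-label
chains, uniform stationary frequencies), transcripts built from founder
allele effects at a local (TSS) marker plus many weak trans-acting effects on
other chromosomes (controllable local and distal heritability), phenotypes
generated *only* through a set of core mediating transcripts (so perfect
mediation holds by construction), and a validation population assembled as F1
crosses of simulated inbred lines that reuses the same founder allele effects
under a distinct kinship structure.

All randomness flows from one master seed; every sub-stream is derived from
``(seed, labeled offset)`` so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import HaplotypeDosages, OmicsMatrix

__all__ = [
    "SimulationConfig",
    "TranscriptomeTruth",
    "simulate_mosaic_genomes",
    "simulate_transcriptome",
    "simulate_phenotypes",
    "simulate_validation_population",
    "simulate_dataset",
]

# labeled RNG sub-stream offsets
_STREAMS = {"genomes": 1, "effects": 2, "expression_noise": 3, "phenotypes": 4, "validation": 5}

CHROM_LENGTH_BP = 100_000_000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic populations.

    ``h2_local``/``h2_distal`` may be scalars (shared by all transcripts) or
    vectors of length ``n_transcripts``. ``phenotype_noise_sd`` is the trait
    noise standard deviation relative to the standard deviation of the
    mediated (core-transcript) component.
    """

    n_individuals: int = 300
    n_markers: int = 1000
    n_chromosomes: int = 10
    n_founders: int = 8
    recomb_prob: float = 0.02
    n_transcripts: int = 2000
    n_core_transcripts: int = 50
    h2_local: float | np.ndarray = 0.15
    h2_distal: float | np.ndarray = 0.15
    core_h2_local: float | None = 0.1
    core_h2_distal: float | None = 0.4
    core_distal_sharing: float = 0.5  # share of core distal variance from one trans program
    n_distal_loci: int = 50
    core_weights: np.ndarray | None = None
    phenotype_noise_sd: float = 0.5
    n_traits: int = 10
    n_lines: int = 40  # inbred lines behind the validation population
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0.0 <= self.recomb_prob <= 1.0:
            raise ValueError("recomb_prob must be a probability")
        if self.n_core_transcripts > self.n_transcripts:
            raise ValueError("n_core_transcripts exceeds n_transcripts")
        hl = np.broadcast_to(np.asarray(self.h2_local, float), (self.n_transcripts,))
        hd = np.broadcast_to(np.asarray(self.h2_distal, float), (self.n_transcripts,))
        if (hl < 0).any() or (hd < 0).any() or (hl + hd > 1 + 1e-12).any():
            raise ValueError("need h2_local, h2_distal >= 0 and h2_local + h2_distal <= 1")

    def h2_vectors(self):
        hl = np.broadcast_to(np.asarray(self.h2_local, float), (self.n_transcripts,)).copy()
        hd = np.broadcast_to(np.asarray(self.h2_distal, float), (self.n_transcripts,)).copy()
        return hl, hd

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def marker_layout(self):
        """Chromosome label and bp position per marker (even spacing)."""
        base = self.n_markers // self.n_chromosomes
        counts = [base + (1 if c < self.n_markers % self.n_chromosomes else 0)
                  for c in range(self.n_chromosomes)]
        chroms, pos = [], []
        for c, m in enumerate(counts, start=1):
            chroms += [str(c)] * m
            pos += list(np.linspace(1_000_000, CHROM_LENGTH_BP - 1_000_000, m).astype(int))
        return np.array(chroms), np.array(pos)


@dataclass
class TranscriptomeTruth:
    """Planted effects and scalings needed to regenerate expression elsewhere."""

    config: SimulationConfig
    feature_ids: list
    tss_marker: np.ndarray
    local_effects: np.ndarray  # n_transcripts x n_founders
    distal_markers: list       # per transcript: array of trans-locus indices
    distal_effects: list       # per transcript: loci x n_founders effect array
    local_center: np.ndarray
    local_scale: np.ndarray
    distal_center: np.ndarray
    distal_scale: np.ndarray
    h2_local: np.ndarray
    h2_distal: np.ndarray
    realized_h2_local: np.ndarray
    realized_h2_distal: np.ndarray
    core_idx: np.ndarray
    core_weights: np.ndarray
    annotations: pd.DataFrame = field(default=None)

    def local_genetic_values(self, dosages: HaplotypeDosages) -> np.ndarray:
        """Scaled local genetic value of every transcript in any population."""
        out = np.empty((dosages.n_individuals, len(self.feature_ids)))
        for j in range(len(self.feature_ids)):
            raw = dosages.dosages[:, self.tss_marker[j], :] @ self.local_effects[j]
            out[:, j] = np.sqrt(self.h2_local[j]) * (raw - self.local_center[j]) / self.local_scale[j]
        return out

    def distal_genetic_values(self, dosages: HaplotypeDosages) -> np.ndarray:
        out = np.empty((dosages.n_individuals, len(self.feature_ids)))
        for j in range(len(self.feature_ids)):
            D = dosages.dosages[:, self.distal_markers[j], :]
            raw = np.einsum("imf,mf->i", D, self.distal_effects[j])
            out[:, j] = np.sqrt(self.h2_distal[j]) * (raw - self.distal_center[j]) / self.distal_scale[j]
        return out


def _founder_chains(rng, n_chains, counts, n_founders, recomb_prob):
    """Markov founder-label chains per chromosome; returns (n_chains, n_markers)."""
    blocks = []
    for m in counts:
        lab = np.empty((n_chains, m), dtype=np.int64)
        lab[:, 0] = rng.integers(n_founders, size=n_chains)
        if m > 1:
            switch = rng.random((n_chains, m - 1)) < recomb_prob
            new = rng.integers(n_founders, size=(n_chains, m - 1))
            for j in range(1, m):
                lab[:, j] = np.where(switch[:, j - 1], new[:, j - 1], lab[:, j - 1])
        blocks.append(lab)
    return np.concatenate(blocks, axis=1)


def simulate_mosaic_genomes(config: SimulationConfig) -> HaplotypeDosages:
    """Outbred-style founder-mosaic diploid genomes.

    Two independent founder-label Markov chains per individual per chromosome
    (switch probability ``recomb_prob`` per adjacent marker interval, new
    label uniform over founders), summed to dosages. Stationary founder
    frequencies are uniform, mimicking a balanced outbreeding design.
    """
    rng = config.rng("genomes")
    chroms, pos = config.marker_layout()
    counts = [int(np.sum(chroms == c)) for c in dict.fromkeys(chroms)]
    n = config.n_individuals
    labels = _founder_chains(rng, 2 * n, counts, config.n_founders, config.recomb_prob)
    hap = np.eye(config.n_founders)[labels]  # (2n, m, f) one-hot
    dosages = hap[:n] + hap[n:]
    marker_map = pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(config.n_markers)], "chrom": chroms, "pos_bp": pos}
    )
    return HaplotypeDosages(
        individual_ids=[f"DO{i:04d}" for i in range(n)],
        marker_map=marker_map,
        dosages=dosages,
    )


def simulate_transcriptome(dosages: HaplotypeDosages, config: SimulationConfig):
    """Transcripts with planted local and distal founder-effect architecture.

    Each transcript sits at a randomly chosen TSS marker; its local term is a
    founder-effect combination at that marker scaled to variance ``h2_local``,
    its distal term the sum of weak founder effects at ``n_distal_loci``
    markers on other chromosomes scaled to ``h2_distal``, plus Gaussian noise
    making up the remainder. Returns the expression matrix and the truth
    record (effects, scalings, realized variance shares).
    """
    rng_eff = config.rng("effects")
    rng_noise = config.rng("expression_noise")
    hl, hd = config.h2_vectors()
    n, m, f = dosages.dosages.shape
    n_t = config.n_transcripts
    core_idx = rng_eff.choice(n_t, size=config.n_core_transcripts, replace=False)
    core_idx.sort()
    # core mediators follow the trait-relevant architecture: mostly distal
    if np.isscalar(config.h2_local) or np.asarray(config.h2_local).ndim == 0:
        if config.core_h2_local is not None:
            hl[core_idx] = config.core_h2_local
    if np.isscalar(config.h2_distal) or np.asarray(config.h2_distal).ndim == 0:
        if config.core_h2_distal is not None:
            hd[core_idx] = config.core_h2_distal
    if ((hl + hd) > 1 + 1e-12).any():
        raise ValueError("core h2 overrides give h2_local + h2_distal > 1")
    chrom_arr = dosages.marker_map["chrom"].astype(str).to_numpy()
    pos_arr = dosages.marker_map["pos_bp"].to_numpy()

    if config.core_weights is not None:
        w = np.asarray(config.core_weights, dtype=float)
        if w.shape != (config.n_core_transcripts,):
            raise ValueError("core_weights must have length n_core_transcripts")
    else:
        # a core mediator has a substantive effect by definition: magnitudes
        # bounded away from zero, random sign
        n_c = config.n_core_transcripts
        w = rng_eff.uniform(0.5, 1.5, n_c) * rng_eff.choice([-1.0, 1.0], n_c)

    tss = rng_eff.integers(m, size=n_t)
    beta_local = rng_eff.standard_normal((n_t, f))
    beta_local -= beta_local.mean(axis=1, keepdims=True)
    n_d = min(config.n_distal_loci, m - 1)

    # shared trans-acting program behind the core module: core transcripts draw
    # part of their distal variance from one convergent set of trans loci, with
    # membership sign matching their trait weight (a coherent endophenotype)
    lam = float(config.core_distal_sharing)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("core_distal_sharing must be in [0, 1]")
    prog_loci = rng_eff.choice(m, size=n_d, replace=False)
    beta_prog = rng_eff.standard_normal((n_d, f))
    beta_prog -= beta_prog.mean(axis=1, keepdims=True)

    distal_markers = []
    distal_effects = []
    is_core = np.zeros(n_t, dtype=bool)
    is_core[core_idx] = True
    core_sign = np.zeros(n_t)
    core_sign[core_idx] = np.sign(w) + (np.sign(w) == 0)
    for j in range(n_t):
        candidates = np.flatnonzero(chrom_arr != chrom_arr[tss[j]])
        if candidates.size == 0:
            candidates = np.array([k for k in range(m) if k != tss[j]])
        loci = rng_eff.choice(candidates, size=min(n_d, candidates.size),
                              replace=candidates.size < n_d)
        eff = rng_eff.standard_normal((loci.size, f))
        eff -= eff.mean(axis=1, keepdims=True)
        distal_markers.append(loci)
        distal_effects.append(eff)

    prog_raw = np.einsum("imf,mf->i", dosages.dosages[:, prog_loci, :], beta_prog)
    prog_scale = max(prog_raw.std(), 1e-12)

    X = np.empty((n, n_t))
    l_center = np.empty(n_t)
    l_scale = np.empty(n_t)
    d_center = np.empty(n_t)
    d_scale = np.empty(n_t)
    rhl = np.zeros(n_t)
    rhd = np.zeros(n_t)
    eps = rng_noise.standard_normal((n, n_t))
    for j in range(n_t):
        if is_core[j] and lam > 0:
            priv_raw = np.einsum("imf,mf->i", dosages.dosages[:, distal_markers[j], :],
                                 distal_effects[j])
            priv_scale = max(priv_raw.std(), 1e-12)
            # fold the shared program into this transcript's stored effects so
            # regeneration in other populations reuses one linear map
            distal_markers[j] = np.concatenate([prog_loci, distal_markers[j]])
            distal_effects[j] = np.concatenate([
                np.sqrt(lam) * core_sign[j] * beta_prog / prog_scale,
                np.sqrt(1.0 - lam) * distal_effects[j] / priv_scale,
            ])
        raw_l = dosages.dosages[:, tss[j], :] @ beta_local[j]
        raw_d = np.einsum("imf,mf->i", dosages.dosages[:, distal_markers[j], :],
                          distal_effects[j])
        l_center[j], l_scale[j] = raw_l.mean(), max(raw_l.std(), 1e-12)
        d_center[j], d_scale[j] = raw_d.mean(), max(raw_d.std(), 1e-12)
        comp_l = np.sqrt(hl[j]) * (raw_l - l_center[j]) / l_scale[j]
        comp_d = np.sqrt(hd[j]) * (raw_d - d_center[j]) / d_scale[j]
        comp_e = np.sqrt(max(0.0, 1.0 - hl[j] - hd[j])) * eps[:, j]
        x = comp_l + comp_d + comp_e
        X[:, j] = x
        v = max(x.var(), 1e-12)
        rhl[j] = comp_l.var() / v
        rhd[j] = comp_d.var() / v

    feature_ids = [f"g{j}" for j in range(n_t)]
    annotations = pd.DataFrame(
        {
            "gene_id": feature_ids,
            "chrom": chrom_arr[tss],
            "tss_bp": pos_arr[tss],
            "tissue": "sim",
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    truth = TranscriptomeTruth(
        config=config,
        feature_ids=feature_ids,
        tss_marker=tss,
        local_effects=beta_local,
        distal_markers=distal_markers,
        distal_effects=distal_effects,
        local_center=l_center,
        local_scale=l_scale,
        distal_center=d_center,
        distal_scale=d_scale,
        h2_local=hl,
        h2_distal=hd,
        realized_h2_local=rhl,
        realized_h2_distal=rhd,
        core_idx=core_idx,
        core_weights=w,
        annotations=annotations,
    )
    expr = OmicsMatrix(
        values=pd.DataFrame(X, index=dosages.individual_ids, columns=feature_ids),
        name="sim",
        feature_annotations=annotations,
    )
    return expr, truth


def simulate_phenotypes(
    transcriptome: OmicsMatrix, truth: TranscriptomeTruth, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> OmicsMatrix:
    """Traits driven only by the core transcripts (perfect mediation by design).

    Every trait is the same core-weighted transcript combination plus
    independent Gaussian noise with standard deviation
    ``phenotype_noise_sd * sd(mediated component)``; there is no direct
    genotype term, so conditioning on the core combination removes every
    genome-phenome correlation.
    """
    if rng is None:
        rng = config.rng("phenotypes")
    X = transcriptome.array
    mediator = X[:, truth.core_idx] @ truth.core_weights
    sd_m = mediator.std()
    if sd_m == 0 and config.phenotype_noise_sd == 0:
        raise ValueError("zero core signal and zero noise would give constant traits")
    noise = rng.standard_normal((X.shape[0], config.n_traits))
    noise_scale = config.phenotype_noise_sd * (sd_m if sd_m > 0 else 1.0)
    traits = mediator[:, None] + noise_scale * noise
    values = pd.DataFrame(
        traits,
        index=transcriptome.individual_ids,
        columns=[f"trait{k}" for k in range(config.n_traits)],
    )
    return OmicsMatrix(values=values, name="phenotypes")


def _inbred_line_haplotypes(rng, config: SimulationConfig):
    chroms, _ = config.marker_layout()
    counts = [int(np.sum(chroms == c)) for c in dict.fromkeys(chroms)]
    return _founder_chains(rng, config.n_lines, counts, config.n_founders, config.recomb_prob)


def simulate_validation_population(truth: TranscriptomeTruth, config2: SimulationConfig):
    """An independent population reusing the planted founder allele effects.

    Genomes are F1 crosses of simulated inbred lines (long homozygous founder
    blocks, RIX-style), so kinship structure differs sharply from the outbred
    discovery population while founder alleles — and hence the planted local
    and distal effects — are shared. Expression and phenotypes are regenerated
    under the new kinship from the truth record's effects and scalings.
    Returns ``(dosages, expression, phenotypes)``; individuals carry a
    ``strain`` column in the expression annotations' ``attrs``.
    """
    cfg1 = truth.config
    if (config2.n_markers, config2.n_chromosomes, config2.n_founders) != (
        cfg1.n_markers, cfg1.n_chromosomes, cfg1.n_founders
    ):
        raise ValueError("validation population marker map incompatible with truth")
    rng = config2.rng("validation")
    lines = _inbred_line_haplotypes(rng, config2)
    n = config2.n_individuals
    pairs = np.empty((n, 2), dtype=np.int64)
    for i in range(n):
        pairs[i] = rng.choice(config2.n_lines, size=2, replace=False)
    hap = np.eye(config2.n_founders)[lines]  # (n_lines, m, f)
    dosages_arr = hap[pairs[:, 0]] + hap[pairs[:, 1]]
    chroms, pos = config2.marker_layout()
    marker_map = pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(config2.n_markers)], "chrom": chroms, "pos_bp": pos}
    )
    strains = [f"L{min(a, b)}xL{max(a, b)}" for a, b in pairs]
    dosages = HaplotypeDosages(
        individual_ids=[f"RIX{i:04d}" for i in range(n)],
        marker_map=marker_map,
        dosages=dosages_arr,
    )

    hl, hd = truth.h2_local, truth.h2_distal
    comp_l = truth.local_genetic_values(dosages)
    comp_d = truth.distal_genetic_values(dosages)
    eps = rng.standard_normal(comp_l.shape)
    X = comp_l + comp_d + np.sqrt(np.clip(1.0 - hl - hd, 0.0, None))[None, :] * eps
    expr = OmicsMatrix(
        values=pd.DataFrame(X, index=dosages.individual_ids, columns=truth.feature_ids),
        name="validation",
        feature_annotations=truth.annotations,
    )
    expr.values.attrs["strain"] = strains
    pheno = simulate_phenotypes(expr, truth, config2, rng=rng)
    return dosages, expr, pheno


def simulate_dataset(config: SimulationConfig):
    """Full discovery-population draw: (dosages, expression, phenotypes, truth)."""
    dosages = simulate_mosaic_genomes(config)
    expr, truth = simulate_transcriptome(dosages, config)
    pheno = simulate_phenotypes(expr, truth, config)
    return dosages, expr, pheno, truth
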