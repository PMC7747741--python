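"""Synthetic methylation fixtures with the statistical structure every
pipeline stage assumes.

Real gene-level methylation vectors, after per-feature min-max scaling,
form a dense cloud of highly similar shapes: co-methylated blocks of
genes share regional signal, annotation overlap makes many gene vectors
near (or exactly) identical, and only a small minority of features are
genuinely isolated.  The generator reproduces that geometry at gene
level and then expands it to probes:

* a **main cloud** of co-methylation blocks (heavy-tailed sizes, genes
  of a block sharing a latent per-sample factor built from a small set
  of archetype profiles), each gene carrying its own residual noise
  level drawn uniformly from a narrow band, so the sorted kNN-distance
  curve has a dense, well-covered body;
* **duplicate families**: small groups of genes that are near-copies of
  one another (annotation-overlap families such as paralog clusters),
  populating the low-distance end of the curve down to ~0;
* **stragglers** (~1%): weakly co-methylated singleton genes occupying
  the thinning upper tail of the distance curve — the region where the
  knee-point rule places eps, and the features a density-based filter
  legitimately trims;
* planted **modules**: the tightest correlated blocks, nested inside the
  differentially methylated gene set (module detection runs on DM genes
  only).  The highest-correlation module is the smallest, so the
  average-correlation maximum and the smaller-module tie-break select
  the same module;
* planted **DM genes**: a symmetric case-vs-control mean shift of
  ``effect_size`` beta units; module latent factors are drawn orthogonal
  to the archetypes and to the group contrast, so they can neither
  shadow background variation nor confound the planted effect;
* planted **outliers**: bimodal artifact-like features whose value in
  every sample is displaced by ``outlier_offset`` cloud SDs with random
  sign (clipping pins them to the beta-value extremes) — far from the
  cloud and from one another, as technically failed probes are.

Gene vectors are expanded to ``probes_per_gene`` probes (gene value plus
probe-level noise), and the probe table gains the artifacts the
preprocessing stage must handle: "rs"/"ch." decoy ids, all-zero and
missing-value probes, and probes annotated to two genes.  Everything is
reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .errors import ValidationError
from .methio import AnnotationMap, BetaMatrix

#: Default planted modules as (size, latent_correlation); the tightest
#: module is the smallest so score maximum and size tie-break agree.
DEFAULT_MODULES = ((15, 0.9991), (20, 0.9982), (30, 0.9970))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; the defaults define the reference conditions.

    ``noise_sd`` is the total per-gene SD in beta units around the 0.5
    baseline; ``outlier_offset`` is in multiples of ``noise_sd``;
    ``effect_size`` is the full case-minus-control mean difference;
    ``modules`` lists ``(size, latent_correlation)`` pairs whose sizes
    sum to at most ``n_dm``.  The structural knobs below control the
    cloud geometry (block sizes, residual-tightness bands) and rarely
    need changing.
    """

    n_genes: int = 2000
    n_case: int = 10
    n_control: int = 10
    outlier_fraction: float = 0.01
    outlier_offset: float = 6.0
    n_dm: int = 65
    effect_size: float = 0.3
    modules: tuple = DEFAULT_MODULES
    noise_sd: float = 0.2
    # cloud geometry
    block_size_range: tuple = (8, 45)
    block_u_range: tuple = (0.025, 0.095)       # residual share sqrt(1-rho)
    duplicate_family_fraction: float = 0.25
    family_size: int = 5
    family_u_max: float = 0.035
    family_concentration: float = 1.5           # power-law pull toward exact copies
    family_jitter: tuple = (1.0, 2.0)
    straggler_fraction: float = 0.01
    straggler_u_range: tuple = (0.12, 0.40)
    n_archetypes: int = 12
    # probe layer
    probes_per_gene: int = 3
    probe_noise_sd: float = 0.005
    decoy_fraction: float = 0.02
    multi_gene_fraction: float = 0.05
    degenerate_fraction: float = 0.003
    beta_mode: str = "clipped_gaussian"  # or "beta"
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.outlier_fraction < 1:
            raise ValidationError("outlier_fraction must be in [0, 1)")
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("need >= 2 samples per group")
        msum = sum(s for s, _ in self.modules)
        if msum > self.n_dm:
            raise ValidationError("module sizes must sum to <= n_dm (modules are DM genes)")
        for s, rho in self.modules:
            if not 0 < rho < 1:
                raise ValidationError("latent_correlation must be in (0, 1)")
            if s < 2:
                raise ValidationError("module size must be >= 2")
        planted = self.n_dm + int(round(self.outlier_fraction * self.n_genes)) \
            + int(round(self.straggler_fraction * self.n_genes))
        if planted > self.n_genes:
            raise ValidationError("planted genes exceed n_genes")
        if self.effect_size / 2 >= 0.5:
            raise ValidationError("effect_size pushes group means out of [0, 1]")
        if self.noise_sd <= 0 or self.probe_noise_sd < 0:
            raise ValidationError("noise SDs must be non-negative (noise_sd positive)")
        if self.beta_mode not in ("clipped_gaussian", "beta"):
            raise ValidationError("beta_mode must be 'clipped_gaussian' or 'beta'")
        if self.family_size < 5:
            raise ValidationError("family_size must be >= 5 (4-NN stays in-family)")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure."""

    outlier_genes: list
    dm_directions: dict          # gene -> "hyper" | "hypo"
    module_members: dict         # module index -> sorted gene list
    module_correlations: dict    # module index -> latent correlation

    @property
    def dm_genes(self) -> list:
        return sorted(self.dm_directions)

    def module_label_of(self) -> dict:
        out = {}
        for m, genes in self.module_members.items():
            for gid in genes:
                out[gid] = m
        return out


def _beta_transform(values: np.ndarray, sd: float) -> np.ndarray:
    """Monotone Gaussian-copula map onto a symmetric Beta marginal with
    mean 0.5 and matching SD; preserves ranks and hence correlations."""
    var = min(sd ** 2, 0.24)
    a = max((1.0 / (4.0 * var) - 1.0) / 2.0, 0.51)
    u = _stats.norm.cdf((values - 0.5) / sd)
    u = np.clip(u, 1e-9, 1 - 1e-9)
    return _stats.beta.ppf(u, a, a)


def generate(spec: SyntheticSpec) -> tuple:
    """Generate ``(BetaMatrix, AnnotationMap, SyntheticTruth)``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_s = spec.n_case + spec.n_control
    n_case = spec.n_case
    sample_ids = [f"S{j + 1:03d}" for j in range(n_s)]
    groups = {s: ("case" if j < n_case else "control")
              for j, s in enumerate(sample_ids)}

    gene_ids = [f"GENE{i + 1:05d}" for i in range(spec.n_genes)]
    s_tot = spec.noise_sd
    z = rng.standard_normal((spec.n_genes, n_s))
    X = np.empty((spec.n_genes, n_s))

    def _normalize(f):
        sd = f.std()
        return f / (sd if sd > 0 else 1.0)

    # Background co-methylation variation lives on a small set of shared
    # archetype sample-profiles; a chance group imbalance in an archetype
    # is exactly what produces correlated false-positive calls in real
    # data.  Planted-module factors are drawn orthogonal to every
    # archetype and to the group-contrast direction, so module membership
    # is a signal of its own rather than a shadow of background
    # variation, and module factors cannot add to or cancel the planted
    # disease effect.
    group_vec = np.r_[np.full(n_case, 1.0), np.full(n_s - n_case, -1.0)]
    archetypes = [_normalize(rng.standard_normal(n_s))
                  for _ in range(spec.n_archetypes)]
    ortho_basis = [group_vec / np.linalg.norm(group_vec)]
    ortho_basis += [a / np.linalg.norm(a) for a in archetypes]

    def planted_factor():
        f = rng.standard_normal(n_s)
        for b in ortho_basis:
            f -= (f @ b) * b
        b = f / np.linalg.norm(f)
        ortho_basis.append(b)
        return _normalize(f)

    def background_factor():
        a = archetypes[int(rng.integers(len(archetypes)))]
        return _normalize(a + 0.15 * rng.standard_normal(n_s))

    blocks: list = []

    def fill_block(idx, u, planted=False):
        u = np.minimum(np.asarray(u, dtype=float), 0.95)
        f = planted_factor() if planted else background_factor()
        load = np.sqrt(1.0 - u ** 2)
        X[idx] = 0.5 + s_tot * (load[:, None] * f[None, :] + u[:, None] * z[idx])
        blocks.append(np.asarray(idx))

    perm = rng.permutation(spec.n_genes)
    cursor = 0
    sign = np.zeros(spec.n_genes)
    dm_directions: dict = {}
    module_members, module_corrs = {}, {}
    for m, (size, rho) in enumerate(spec.modules):
        idx = perm[cursor:cursor + size]
        cursor += size
        u_m = np.sqrt(1.0 - rho)
        fill_block(idx, np.full(size, u_m) * rng.uniform(0.9, 1.1, size=size),
                   planted=True)
        d = 1 if m % 2 == 0 else -1
        sign[idx] = d
        module_members[m] = sorted(gene_ids[i] for i in idx)
        module_corrs[m] = rho
        for i in idx:
            dm_directions[gene_ids[i]] = "hyper" if d > 0 else "hypo"
    # any DM genes beyond the modules come in small shifted blocks
    while cursor < spec.n_dm:
        bs = min(5, spec.n_dm - cursor)
        idx = perm[cursor:cursor + bs]
        cursor += bs
        fill_block(idx, rng.uniform(*spec.block_u_range, size=bs), planted=True)
        d = int(rng.choice([-1, 1]))
        sign[idx] = d
        for i in idx:
            dm_directions[gene_ids[i]] = "hyper" if d > 0 else "hypo"

    n_out = int(round(spec.outlier_fraction * spec.n_genes))
    out_idx = perm[cursor:cursor + n_out]
    cursor += n_out
    n_strag = int(round(spec.straggler_fraction * spec.n_genes))
    strag_idx = perm[cursor:cursor + n_strag]
    cursor += n_strag

    n_fam_genes = int(round(spec.duplicate_family_fraction * spec.n_genes))
    n_fam_genes = min(n_fam_genes, spec.n_genes - cursor)
    for _ in range(n_fam_genes // spec.family_size):
        idx = perm[cursor:cursor + spec.family_size]
        cursor += spec.family_size
        ub = spec.family_u_max * rng.random() ** spec.family_concentration
        fill_block(idx, ub * rng.uniform(*spec.family_jitter, size=spec.family_size))

    bg = perm[cursor:]
    p = 0
    lo_b, hi_b = spec.block_size_range
    # heavy-tailed block sizes (P(s) ~ 1/s^2): co-methylation domains
    # come in many small and a few large blocks
    sizes = np.arange(lo_b, hi_b + 1)
    size_p = (1.0 / sizes.astype(float) ** 2)
    size_p /= size_p.sum()
    while p < bg.size:
        bs = int(rng.choice(sizes, p=size_p))
        idx = bg[p:p + bs]
        p += bs
        fill_block(idx, rng.uniform(*spec.block_u_range, size=idx.size))

    for i in strag_idx:
        u = rng.uniform(*spec.straggler_u_range)
        f = background_factor()
        X[i] = 0.5 + s_tot * (np.sqrt(1 - u * u) * f + u * z[i])

    # outliers: near-flat baseline, every sample displaced to an extreme
    X[out_idx] = 0.5 + 0.1 * s_tot * rng.standard_normal((n_out, n_s))
    X[out_idx] += rng.choice([-1.0, 1.0], size=(n_out, n_s)) * spec.outlier_offset * s_tot

    X += sign[:, None] * np.r_[np.full(n_case, 0.5), np.full(n_s - n_case, -0.5)][None, :] \
        * spec.effect_size
    if spec.beta_mode == "beta":
        plain = np.ones(spec.n_genes, dtype=bool)
        plain[out_idx] = False
        X[plain] = _beta_transform(X[plain], s_tot)
    X = np.clip(X, 0.0, 1.0)

    truth = SyntheticTruth(
        outlier_genes=sorted(gene_ids[i] for i in out_idx),
        dm_directions=dm_directions,
        module_members=module_members,
        module_correlations=module_corrs,
    )

    beta, ann = _expand_to_probes(spec, rng, X, gene_ids, sample_ids, groups,
                                  perm, blocks, set(dm_directions) | set(truth.outlier_genes))
    return beta, ann, truth


def _expand_to_probes(spec, rng, X, gene_ids, sample_ids, groups, perm,
                      blocks, planted_genes):
    """Expand gene vectors to probes and build the annotation table."""
    n_genes, n_s = X.shape
    n_main = n_genes * spec.probes_per_gene
    probe_vals = np.repeat(X, spec.probes_per_gene, axis=0)
    if spec.probe_noise_sd > 0:
        probe_vals = probe_vals + rng.standard_normal(probe_vals.shape) * spec.probe_noise_sd
        probe_vals = np.clip(probe_vals, 0.0, 1.0)
    probe_ids = [f"cg{i + 1:08d}" for i in range(n_main)]
    probe_gene = np.repeat(np.arange(n_genes), spec.probes_per_gene)
    entries = {pid: {gene_ids[gi]} for pid, gi in zip(probe_ids, probe_gene)}

    # many-to-many decoration: a probe may also annotate a neighbor gene
    # of the same co-methylation block (shared CpG islands); planted
    # truth genes are left undecorated
    mates = {}
    for blk in blocks:
        if blk.size < 2:
            continue
        for i in blk:
            if gene_ids[i] not in planted_genes:
                mates[int(i)] = blk
    bg_pool = [gene_ids[i] for i in sorted(mates)]
    if spec.multi_gene_fraction > 0 and mates:
        rows = np.flatnonzero(np.isin(probe_gene, np.array(sorted(mates))))
        n_multi = min(int(round(spec.multi_gene_fraction * n_main)), rows.size)
        for r in rng.choice(rows, size=n_multi, replace=False):
            gi = int(probe_gene[r])
            blk = mates[gi]
            other = int(rng.choice(blk))
            if other != gi and gene_ids[other] not in planted_genes:
                entries[probe_ids[r]].add(gene_ids[other])

    extra_rows, extra_ids = [], []
    n_deg = int(round(spec.degenerate_fraction * n_main))
    for j in range(n_deg):
        pid = f"cg9{j + 1:07d}"
        if j % 2 == 0:
            row = np.zeros(n_s)
        else:
            row = np.clip(0.5 + rng.standard_normal(n_s) * spec.noise_sd, 0, 1)
            row[int(rng.integers(n_s))] = np.nan
        extra_rows.append(row)
        extra_ids.append(pid)
        entries[pid] = {bg_pool[int(rng.integers(len(bg_pool)))]}
    n_dec = int(round(spec.decoy_fraction * n_main))
    for j in range(n_dec):
        pid = f"rs{j + 1:06d}" if j % 2 == 0 else f"ch.{(j % 22) + 1}.{j + 1:06d}F"
        extra_rows.append(np.clip(0.5 + rng.standard_normal(n_s) * spec.noise_sd, 0, 1))
        extra_ids.append(pid)
        entries[pid] = {bg_pool[int(rng.integers(len(bg_pool)))]}

    all_ids = probe_ids + extra_ids
    if extra_rows:
        all_vals = np.vstack([probe_vals] + [np.asarray(r)[None, :] for r in extra_rows])
    else:
        all_vals = probe_vals
    order = rng.permutation(len(all_ids))
    all_ids = [all_ids[i] for i in order]
    all_vals = all_vals[order]
    return BetaMatrix(all_ids, sample_ids, all_vals, groups), AnnotationMap(entries)


def small_preset(seed: int = 0) -> SyntheticSpec:
    """Reference conditions at desk scale (2000 genes, 10 vs 10 samples)."""
    return SyntheticSpec(seed=seed)


def paper_shaped_preset(seed: int = 0) -> SyntheticSpec:
    """Array-scale conditions: ~20,000 genes, 9 cases vs 11 controls,
    module sizes in the range seen in real module detection."""
    return SyntheticSpec(
        n_genes=20000, n_case=9, n_control=11,
        n_dm=370,
        modules=((89, 0.9991), (120, 0.9982), (161, 0.9970)),
        seed=seed,
    )
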