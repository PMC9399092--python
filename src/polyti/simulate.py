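"""Synthetic polysome-profiling data with known ground truth.

The generator emulates the statistical structure the analysis assumes:
per-gene ORF lengths and mRNA abundances, a latent translation index per
(strain, condition) whose log2 depends linearly on standardized log ORF
length with strain-specific slopes and a drug x length interaction, a
two-compartment allocation of each gene's mRNA between heavy and light
polysome fractions (p_heavy = ti / (1 + ti), the minimal model consistent
with the TI's definition as a heavy/light ratio), and Negative-Binomial
sequencing counts (Poisson in the dispersion -> 0 limit). Matched Ct and
peptide-intensity tables are generated from the same latent state.

Category labels: a "cell periphery" label is assigned with probability
increasing in ORF length — long genes carry it more often, so a positive
length effect makes the over-translated set enrich for it — plus two
length-independent background categories so the enrichment stage has a
multiple-testing burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import FractionCounts, GeneAnnotation, SampleManifest

CELL_PERIPHERY = "cell periphery"
#: length-independent background categories: (label, probability)
BACKGROUND_CATEGORIES = (("cytoplasm", 0.30), ("nucleus", 0.20))


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic polysome-profiling experiment.

    Defaults encode the study conditions the pipeline targets: two
    biological replicates per (strain, condition, fraction), a wild-type
    strain with no length preference and a ul30bb strain whose log2 TI
    gains 0.4 per standard deviation of log ORF length, strengthened by a
    further 0.2 under drug treatment. Lengths are LogNormal(7.2, 0.6) in
    log-nt (median ~1339 nt, near the mid-size yeast ORF); abundances are
    LogNormal on the log-TPM scale.
    """

    n_genes: int = 2000
    length_logmean: float = 7.2
    length_logsd: float = 0.6
    abundance_logmean: float = 4.0
    abundance_logsd: float = 1.2
    ti_base_log2: float = 0.0
    beta_length: dict = field(
        default_factory=lambda: {"WT": 0.0, "ul30bb": 0.4}
    )
    delta_drug: dict = field(
        default_factory=lambda: {"WT": 0.0, "ul30bb": 0.2}
    )
    ti_noise_sd: float = 0.25
    library_size: int = 5_000_000
    dispersion: float = 0.05
    frac_category_cp: float = 0.15
    conditions: tuple = ("untreated", "treated")
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 10:
            raise ParameterError("n_genes must be >= 10")
        for name in ("length_logsd", "abundance_logsd"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.ti_noise_sd < 0:
            raise ParameterError("ti_noise_sd must be >= 0")
        if self.library_size <= 0:
            raise ParameterError("library_size must be > 0")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if not 0 <= self.frac_category_cp <= 1:
            raise ParameterError("frac_category_cp must lie in [0, 1]")
        if set(self.beta_length) != set(self.delta_drug):
            raise ParameterError(
                "beta_length and delta_drug must cover the same strains"
            )

    @property
    def strains(self) -> list[str]:
        return list(self.beta_length)


@dataclass(frozen=True)
class TrueState:
    """Latent per-gene quantities behind a simulated dataset.

    ``genes``: orf_length_nt, true_abundance (expected TPM scale),
    categories. ``true_ti``: linear-scale TI per (strain, condition)
    MultiIndex column.
    """

    genes: pd.DataFrame
    true_ti: pd.DataFrame

    def p_heavy(self) -> pd.DataFrame:
        """Heavy-fraction allocation probability ti / (1 + ti)."""
        return self.true_ti / (1.0 + self.true_ti)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative-Binomial draws with var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_dataset(
    params: GeneratorParams,
) -> tuple[GeneAnnotation, TrueState, FractionCounts, SampleManifest]:
    """Generate annotation, latent truth, fraction counts and a manifest.

    log2 ti(g, s, c) = ti_base + beta_length[s] * z_g
                       + 1{c = treated} * delta_drug[s] * z_g
                       + Normal(0, ti_noise_sd)

    with z_g the standardized log ORF length. Expected counts per sample
    are library_size times the renormalized abundance-weighted allocation
    share (p_heavy for heavy samples, 1 - p_heavy for light, 1 for total).
    The same seed reproduces the tables exactly.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    log_len = rng.normal(params.length_logmean, params.length_logsd, n)
    lengths = np.maximum(75, (np.round(np.exp(log_len) / 3) * 3).astype(np.int64))
    z = (np.log(lengths) - np.log(lengths).mean()) / np.log(lengths).std()
    abundance = np.exp(rng.normal(params.abundance_logmean, params.abundance_logsd, n))

    # latent TI per (strain, condition)
    ti_cols = {}
    for strain in params.strains:
        for condition in params.conditions:
            drug = 1.0 if condition == "treated" else 0.0
            mu = (
                params.ti_base_log2
                + params.beta_length[strain] * z
                + drug * params.delta_drug[strain] * z
            )
            noise = rng.normal(0.0, params.ti_noise_sd, n)
            ti_cols[(strain, condition)] = 2.0 ** (mu + noise)
    true_ti = pd.DataFrame(ti_cols, index=gene_ids)
    true_ti.columns = pd.MultiIndex.from_tuples(
        true_ti.columns, names=["strain", "condition"]
    )

    # category labels: cell periphery biased toward long genes
    weight = np.exp(z)
    p_cp = np.clip(params.frac_category_cp * n * weight / weight.sum(), 0.0, 1.0)
    is_cp = rng.random(n) < p_cp
    bg_draws = {
        label: rng.random(n) < prob for label, prob in BACKGROUND_CATEGORIES
    }
    categories = []
    for i in range(n):
        cats = [CELL_PERIPHERY] if is_cp[i] else []
        cats += [label for label in bg_draws if bg_draws[label][i]]
        categories.append(tuple(cats))

    contexts = _random_contexts(rng, n)
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "orf_length_nt": lengths,
                "start_context": contexts,
                "categories": categories,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    truth = TrueState(
        genes=pd.DataFrame(
            {
                "orf_length_nt": lengths,
                "true_abundance": abundance,
                "categories": categories,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        true_ti=true_ti,
    )

    # counts: one column per (strain, condition, fraction, replicate)
    manifest_rows = []
    count_cols = {}
    for strain in params.strains:
        for condition in params.conditions:
            p_heavy = np.asarray(
                true_ti[(strain, condition)] / (1.0 + true_ti[(strain, condition)])
            )
            for fraction in ("light", "heavy", "total"):
                share = {
                    "heavy": abundance * p_heavy,
                    "light": abundance * (1.0 - p_heavy),
                    "total": abundance,
                }[fraction]
                expected = params.library_size * share / share.sum()
                for rep in range(1, params.n_replicates + 1):
                    sid = f"{strain}_{condition}_{fraction}_{rep}"
                    manifest_rows.append((sid, strain, condition, fraction, rep))
                    count_cols[sid] = _draw_counts(rng, expected, params.dispersion)
    manifest = SampleManifest(
        pd.DataFrame(
            manifest_rows,
            columns=["sample_id", "strain", "condition", "fraction", "replicate"],
        )
    )
    counts = FractionCounts(
        pd.DataFrame(count_cols, index=pd.Index(gene_ids, name="gene_id")).astype(
            np.int64
        ),
        manifest,
    )
    return annotation, truth, counts, manifest


def _random_contexts(rng: np.random.Generator, n: int) -> list[str]:
    """Random but reproducible 12-mer start contexts (6 nt + ATG + 3 nt)."""
    bases = np.array(list("ACGT"))
    up = rng.integers(0, 4, size=(n, 6))
    down = rng.integers(0, 4, size=(n, 3))
    return [
        "".join(bases[u]) + "ATG" + "".join(bases[d])
        for u, d in zip(up, down)
    ]


# ---------------------------------------------------------------------------
# Matched qPCR and peptide tables


def simulate_qpcr(
    state: TrueState,
    genes: list[str],
    control: str,
    seed: int,
    ct_ref: float = 20.0,
    noise_sd: float = 0.1,
    n_tech_reps: int = 3,
) -> pd.DataFrame:
    """Ct table for the given genes across heavy/light fraction samples.

    For every (strain, condition) of the latent state, two fraction
    samples are produced; the relative quantity of a gene in a fraction is
    abundance x allocation share, and Ct = ct_ref - log2(quantity) +
    Normal(0, noise_sd), with 3 technical replicates per well.
    """
    rng = np.random.default_rng(seed)
    for g in list(genes) + [control]:
        if g not in state.genes.index:
            raise KeyError(f"gene {g!r} not in the simulated state")
    rows = []
    all_genes = list(dict.fromkeys(list(genes) + [control]))
    for strain, condition in state.true_ti.columns:
        ti = state.true_ti[(strain, condition)]
        p_heavy = ti / (1.0 + ti)
        for fraction, share in (("heavy", p_heavy), ("light", 1.0 - p_heavy)):
            sid = f"{strain}_{condition}_{fraction}"
            for g in all_genes:
                quantity = state.genes.loc[g, "true_abundance"] * share[g]
                base_ct = ct_ref - np.log2(quantity)
                for rep in range(1, n_tech_reps + 1):
                    rows.append(
                        (
                            sid,
                            f"{strain}:{condition}",
                            g,
                            base_ct + rng.normal(0.0, noise_sd),
                            rep,
                        )
                    )
    return pd.DataFrame(
        rows, columns=["sample_id", "condition_label", "gene_id", "ct", "tech_rep"]
    )


def simulate_peptides(
    acetyl_frac: dict,
    total_intensity: float,
    cv: float,
    seed: int,
    n_samples: int = 1,
) -> pd.DataFrame:
    """Peptide-intensity table with a specified acetylated share per paralog.

    Each (sample, paralog, acetyl-state) intensity is the expected share of
    ``total_intensity`` perturbed by mean-one log-normal noise with the
    given coefficient of variation, so the expected acetylated share
    equals ``acetyl_frac``. A fraction of exactly 0 or 1 yields an exactly
    zero complementary intensity.
    """
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    for paralog, frac in acetyl_frac.items():
        if not 0.0 <= frac <= 1.0:
            raise ParameterError(f"acetyl_frac[{paralog!r}] must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for s in range(1, n_samples + 1):
        sid = f"S{s}"
        for paralog, frac in acetyl_frac.items():
            for acetylated, share in ((True, frac), (False, 1.0 - frac)):
                if share == 0.0:
                    intensity = 0.0
                else:
                    noise = np.exp(rng.normal(-(sigma**2) / 2.0, sigma))
                    intensity = total_intensity * share * noise
                rows.append((sid, paralog, acetylated, "", intensity))
    return pd.DataFrame(
        rows, columns=["sample_id", "paralog", "acetylated", "fraction", "intensity"]
    )


def write_truth(state: TrueState, path) -> None:
    """Flatten the latent state to a TSV for recovery tests."""
    out = state.genes.drop(columns=["categories"]).copy()
    out["categories"] = state.genes["categories"].map(";".join)
    for strain, condition in state.true_ti.columns:
        out[f"true_ti.{strain}.{condition}"] = state.true_ti[(strain, condition)]
    out.to_csv(path, sep="\t", float_format="%.6g")
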