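"""Synthetic-data generators with known ground truth for every pipeline stage.

Emulated structures: multi-dataset tumour/non-tumour expression cohorts with
an embedded UP/DN signature effect, survival times whose hazard depends on an
activation score, tissue images of non-overlapping cells with concentric
nuclei and phenotype-dependent lognormal marker intensities, mouse/human CNA
call sets with a tunable concordance fraction, and per-cell QC feature tables
with planted violations. All generators are bit-reproducible under a fixed
seed and return the ground truth needed to score the downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionCohort, LabelImage, SignaturePair

TUMOUR, NON_TUMOUR = "tumour", "non-tumour"

DEFAULT_PHENOTYPE_MIX = {"tumour_cell": 0.5, "t_cell": 0.3, "myeloid": 0.2}


@dataclass
class SimulationSpec:
    """Knobs of the synthetic study; defaults mirror the emulated cohorts.

    ``effect_size`` is the standardized mean shift applied to UP genes in
    tumour samples (DN genes get the negated shift); ``hazard_beta`` is the
    log-hazard per standard deviation of the activation score.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 50
    n_datasets: int = 22
    n_up_genes: int = 100
    n_dn_genes: int = 50
    effect_size: float = 0.8
    noise_sd: float = 1.0
    tau: float = 0.0  # between-dataset SD of the true effect
    hazard_beta: float = 1.0
    censor_rate: float = 0.3
    median_survival_months: float = 30.0
    n_cells: int = 50
    cell_radius_px: int = 5
    phenotype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_MIX)
    )
    marker_log_sd: float = 0.5
    marker_separation_sd: float = 4.0  # positive vs negative means, in log-SD units
    n_regions: int = 20
    concordance_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples_per_group", "n_datasets", "n_cells", "n_regions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not 0 <= self.concordance_frac <= 1:
            raise ValueError("concordance_frac must lie in [0, 1]")
        if abs(sum(self.phenotype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("phenotype proportions must sum to 1")
        if self.n_up_genes + self.n_dn_genes > self.n_genes:
            raise ValueError("signature larger than the gene universe")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(1, n + 1)]


# ------------------------------------------------------------- expression


def gen_expression_cohort(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    dataset: str = "sim",
    baseline_shift: float = 0.0,
    effect_size: float | None = None,
) -> tuple[ExpressionCohort, SignaturePair]:
    """One tumour/non-tumour cohort with an embedded UP/DN signature effect.

    Gaussian log-expression around per-gene baselines; in tumour samples UP
    genes shift by +effect_size*noise_sd and DN genes by the negated shift.
    """
    rng = rng if rng is not None else spec.rng()
    effect = spec.effect_size if effect_size is None else effect_size
    genes = _gene_ids(spec.n_genes)
    up = genes[: spec.n_up_genes]
    dn = genes[spec.n_up_genes : spec.n_up_genes + spec.n_dn_genes]
    sig = SignaturePair(up=up, dn=dn, name=f"{dataset}_truth")

    n = spec.n_samples_per_group
    samples = [f"{dataset}_T{i:03d}" for i in range(n)] + [
        f"{dataset}_N{i:03d}" for i in range(n)
    ]
    base = rng.normal(0.0, 2.0, size=spec.n_genes)[:, None] + baseline_shift
    x = base + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, 2 * n))
    shift = effect * spec.noise_sd
    x[: spec.n_up_genes, :n] += shift
    x[spec.n_up_genes : spec.n_up_genes + spec.n_dn_genes, :n] -= shift
    expr = pd.DataFrame(x, index=genes, columns=samples)
    groups = pd.Series([TUMOUR] * n + [NON_TUMOUR] * n, index=samples, name="group")
    return ExpressionCohort(expr=expr, groups=groups, dataset=dataset), sig


def gen_multi_dataset(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[list[ExpressionCohort], SignaturePair, np.ndarray]:
    """A panel of cohorts sharing one true effect (plus optional heterogeneity).

    Each dataset gets an independent baseline shift; the per-dataset true
    effect is effect_size + N(0, tau^2). Returns cohorts, the shared signature
    and the per-dataset true effects.
    """
    if spec.n_datasets < 2:
        raise ValueError("need at least 2 datasets")
    rng = rng if rng is not None else spec.rng()
    cohorts = []
    true_effects = spec.effect_size + rng.normal(0.0, spec.tau, size=spec.n_datasets)
    sig = None
    for d, eff in enumerate(true_effects):
        cohort, sig = gen_expression_cohort(
            spec,
            rng=rng,
            dataset=f"ds{d + 1:02d}",
            baseline_shift=float(rng.normal(0.0, 1.0)),
            effect_size=float(eff),
        )
        cohorts.append(cohort)
    return cohorts, sig, true_effects


def gen_score_panel(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-dataset two-group score samples with planted standardized shift.

    Emulates the per-dataset enrichment-score contrast directly at the score
    level: tumour ~ N(mu_d + delta_d, 1), control ~ N(mu_d, 1) with
    delta_d = effect_size + N(0, tau^2), so the true SMD equals effect_size
    on average. Substrate for meta-analysis recovery tests.
    """
    rng = rng if rng is not None else spec.rng()
    n = spec.n_samples_per_group
    panel = []
    for _ in range(spec.n_datasets):
        mu = rng.normal(0.0, 1.0)
        delta = spec.effect_size + rng.normal(0.0, spec.tau)
        panel.append(
            (rng.normal(mu + delta, 1.0, size=n), rng.normal(mu, 1.0, size=n))
        )
    return panel


# --------------------------------------------------------------- survival


def gen_survival_cohort(
    spec: SimulationSpec,
    scores,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival times whose hazard follows the activation score.

    Hazard h0 * exp(hazard_beta * z(score)) with h0 set so a zero-score
    patient has the configured median survival. A ``censor_rate`` fraction of
    patients is censored at a uniform time before their event; times are in
    months.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if not np.isfinite(spec.hazard_beta):
        raise ValueError("hazard_beta must be finite")
    rng = rng if rng is not None else spec.rng()
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    h0 = np.log(2.0) / spec.median_survival_months
    hazard = h0 * np.exp(spec.hazard_beta * z)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(scores.size) < spec.censor_rate
    time = np.where(censored, rng.random(scores.size) * t_event, t_event)
    return pd.DataFrame(
        {
            "time_months": time,
            "event": np.where(censored, 0, 1).astype(int),
            "score": scores,
        },
        index=[f"p{i:04d}" for i in range(scores.size)],
    )


# ------------------------------------------------------------------ tissue


def _disc_offsets(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    keep = dy**2 + dx**2 <= radius**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def gen_tissue_image(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    max_tries: int | None = None,
) -> tuple[LabelImage, LabelImage, pd.DataFrame]:
    """Tissue of non-overlapping disc cells with concentric nuclear discs.

    Returns the cell and nucleus label images plus a ground-truth table with
    each cell's centroid, area, phenotype and lognormal marker intensities
    (one marker per phenotype; positive cells sit ``marker_separation_sd``
    log-SDs above negative cells).
    """
    rng = rng if rng is not None else spec.rng()
    r = spec.cell_radius_px
    side = int(np.ceil(np.sqrt(spec.n_cells)) * (4 * r + 4))
    max_tries = max_tries or 200 * spec.n_cells

    centers: list[tuple[int, int]] = []
    tries = 0
    min_d2 = (2 * r + 2) ** 2
    while len(centers) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells in "
                f"{side}x{side} px after {max_tries} tries; lower n_cells"
            )
        cy = int(rng.integers(r + 1, side - r - 1))
        cx = int(rng.integers(r + 1, side - r - 1))
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_d2 for y, x in centers):
            centers.append((cy, cx))

    cells = np.zeros((side, side), dtype=np.int32)
    nuclei = np.zeros((side, side), dtype=np.int32)
    cell_off = _disc_offsets(r)
    nuc_off = _disc_offsets(max(1, r // 2))
    for i, (cy, cx) in enumerate(centers, start=1):
        cells[cy + cell_off[:, 0], cx + cell_off[:, 1]] = i
        nuclei[cy + nuc_off[:, 0], cx + nuc_off[:, 1]] = i

    phenotypes = list(spec.phenotype_mix)
    probs = np.array([spec.phenotype_mix[p] for p in phenotypes])
    assigned = rng.choice(len(phenotypes), size=spec.n_cells, p=probs)

    truth = pd.DataFrame(
        {
            "centroid_row": [c[0] for c in centers],
            "centroid_col": [c[1] for c in centers],
            "area_px": len(cell_off),
            "nucleus_area_px": len(nuc_off),
            "phenotype": [phenotypes[k] for k in assigned],
        },
        index=pd.RangeIndex(1, spec.n_cells + 1, name="cell_id"),
    )
    sigma = spec.marker_log_sd
    for k, pheno in enumerate(phenotypes):
        mu = np.where(assigned == k, spec.marker_separation_sd * sigma, 0.0)
        truth[f"{pheno}_marker"] = np.exp(rng.normal(mu, sigma))
    return LabelImage(labels=cells), LabelImage(labels=nuclei), truth


def render_intensity_planes(
    cells: LabelImage, truth: pd.DataFrame, markers: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Paint per-cell marker intensities onto image planes (uniform per cell)."""
    markers = markers or [c for c in truth.columns if c.endswith("_marker")]
    planes = {}
    labels = truth.index.to_numpy()
    for marker in markers:
        lut = np.zeros(int(labels.max()) + 1)
        lut[labels] = truth[marker].to_numpy()
        planes[marker] = lut[cells.labels]
    return planes


# --------------------------------------------------------------------- CNA


def gen_cna_dataset(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Mouse CNA regions, a 1:1 homology map and human carrier frequencies.

    Exactly round(concordance_frac * n_regions) pairs (the first ones, by
    deterministic assignment) get a same-type human frequency drawn strictly
    above the 5% threshold; the rest are drawn strictly below. Returns mouse
    regions, homology map, human regions and the boolean concordance truth.
    """
    rng = rng if rng is not None else spec.rng()
    n = spec.n_regions
    n_conc = int(round(spec.concordance_frac * n))
    concordant = np.zeros(n, dtype=bool)
    concordant[:n_conc] = True

    length = 1_000_000
    cna_types = np.where(np.arange(n) % 2 == 0, "gain", "loss")
    mouse = pd.DataFrame(
        {
            "chrom": [f"chr{(i % 19) + 1}" for i in range(n)],
            "start": np.arange(n) * 2 * length,
            "end": np.arange(n) * 2 * length + length,
            "cna_type": cna_types,
            "name": [f"m{i:03d}" for i in range(n)],
        }
    )
    freq_hi = 0.06 + 0.4 * rng.random(n)
    freq_lo = 0.049 * rng.random(n)
    human = pd.DataFrame(
        {
            "chrom": [f"chr{(i % 22) + 1}" for i in range(n)],
            "start": np.arange(n) * 2 * length,
            "end": np.arange(n) * 2 * length + length,
            "cna_type": cna_types,
            "frequency": np.where(concordant, freq_hi, freq_lo),
            "name": [f"h{i:03d}" for i in range(n)],
        }
    )
    homology = pd.DataFrame({"mouse_key": mouse["name"], "human_key": human["name"]})
    return mouse, homology, human, concordant


# ------------------------------------------------------------- QC features


def gen_sc_feature_table(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    violations: dict[str, int] | None = None,
    markers: tuple[str, ...] = ("cd8", "ldha"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell QC feature table with a configurable count of planted violations.

    Clean cells fall comfortably inside the default QC windows; violating
    cells trip exactly one named rule each (area_low, area_high, nuclear_dim,
    prop_low, prop_high). Returns the table and the per-cell truth label
    ('clean' or the rule tripped).
    """
    rng = rng if rng is not None else spec.rng()
    violations = violations or {}
    unknown = set(violations) - {"area_low", "area_high", "nuclear_dim", "prop_low", "prop_high"}
    if unknown:
        raise ValueError(f"unknown QC rules: {sorted(unknown)}")

    n_clean = spec.n_cells
    rows = {
        "area_px": rng.uniform(100, 1500, size=n_clean),
        "nuclear_sum_au": rng.uniform(20, 200, size=n_clean),
        "nuclear_prop_pct": rng.uniform(10, 90, size=n_clean),
    }
    df = pd.DataFrame(rows)
    labels = ["clean"] * n_clean

    planted = {
        "area_low": {"area_px": 50.0},
        "area_high": {"area_px": 5000.0},
        "nuclear_dim": {"nuclear_sum_au": 5.0},
        "prop_low": {"nuclear_prop_pct": 0.1},
        "prop_high": {"nuclear_prop_pct": 99.9},
    }
    extra = []
    for rule, count in violations.items():
        for _ in range(count):
            row = {
                "area_px": float(rng.uniform(100, 1500)),
                "nuclear_sum_au": float(rng.uniform(20, 200)),
                "nuclear_prop_pct": float(rng.uniform(10, 90)),
            }
            row.update(planted[rule])
            extra.append(row)
            labels.append(rule)
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    for marker in markers:
        df[marker] = np.exp(rng.normal(0.0, 1.0, size=len(df)))
    df.index = [f"cell{i:05d}" for i in range(len(df))]
    return df, pd.Series(labels, index=df.index, name="qc_truth")
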