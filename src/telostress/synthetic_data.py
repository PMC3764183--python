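"""Synthetic study generators with known ground truth.

Every input the pipeline consumes can be generated here with planted signal:

- expression matrices with condition-specific differentially expressed genes
  on the 4-control / 3-stress array design, plus Present/Marginal/Absent
  detection calls;
- stochastic-block-model gene networks with an optionally planted set of
  mutually proximal TLM genes that are DE under one stress;
- mutant screen tables where the length change is linear in initial length
  with planted over/under-responsive outliers;
- lane densitometry profiles from a known log-linear migration model;
- ChIP quantification quadruples at a known true fold change.

All generators are deterministic in their seed. Ground truth travels in a
SyntheticTruth record so downstream parameter-recovery tests can score
themselves against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .expression_de import ExpressionBundle
from .network_proximity import GeneNetwork
from .responsiveness_screen import ScreenTable
from .telquant import LaneProfile, calibrate
from .chip_quant import ChipMeasurement

__all__ = [
    "SyntheticTruth",
    "gen_expression",
    "gen_network",
    "gen_screen",
    "gen_lane",
    "gen_chip_counts",
    "DEFAULT_MARKERS",
    "INITIAL_LENGTH_RANGE",
]

# marker bands of the original assay: (migration position, size in bp)
DEFAULT_MARKERS = ((10.0, 2044.0), (50.0, 779.0))
# screened mutants' initial telomere-repeat lengths, bp (wild type ~350 bp
# of repeats; the range brackets short and long maintenance mutants)
INITIAL_LENGTH_RANGE = (150.0, 450.0)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    seed: int
    de_genes_per_stress: dict = field(default_factory=dict)
    planted_proximal_set: set = field(default_factory=set)
    screen_outliers: set = field(default_factory=set)
    true_slope: float | None = None
    true_intercept: float | None = None
    true_fragment_sizes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def _require_positive(**params) -> None:
    for name, value in params.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def gen_expression(
    n_genes: int = 1000,
    n_control: int = 4,
    n_stress: int = 3,
    stresses=("ethanol", "caffeine", "temp37", "h2o2"),
    de_fraction: float = 0.05,
    effect: float = 1.5,
    sigma: float = 0.5,
    absent_rate: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionBundle, SyntheticTruth]:
    """Generate a normalized expression bundle with planted DE genes.

    Per-gene baselines are uniform on the typical post-normalization log2
    range [4, 12]; noise is i.i.d. Gaussian with SD `sigma` on that scale.
    Per stress, exactly round(de_fraction * n_genes) genes get their mean in
    that stress's samples shifted by +/- `effect` (sign per gene by fair
    coin). Detection-call 'A' is drawn i.i.d. at `absent_rate`, independent
    of DE status; the rest are 'P' with a 5% admixture of 'M'.
    """
    _require_positive(n_genes=n_genes, n_control=n_control, n_stress=n_stress,
                      sigma=sigma)
    if n_genes < 50:
        raise ValueError(f"n_genes must be >= 50, got {n_genes}")
    if not (0.0 <= de_fraction < 1.0):
        raise ValueError(f"de_fraction must be in [0, 1), got {de_fraction}")
    if not (0.0 <= absent_rate < 1.0):
        raise ValueError(f"absent_rate must be in [0, 1), got {absent_rate}")
    stresses = list(stresses)
    rng = np.random.default_rng(seed)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"control_{j + 1}" for j in range(n_control)]
    labels = ["control"] * n_control
    for s in stresses:
        samples += [f"{s}_{j + 1}" for j in range(n_stress)]
        labels += [s] * n_stress

    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    x = baseline[:, None] + rng.normal(0.0, sigma, size=(n_genes, len(samples)))

    n_de = round(de_fraction * n_genes)
    truth = SyntheticTruth(seed=seed)
    col_of = {s: i for i, s in enumerate(samples)}
    for s in stresses:
        planted_idx = rng.choice(n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        cols = [col_of[f"{s}_{j + 1}"] for j in range(n_stress)]
        for gi, sign in zip(planted_idx, signs):
            x[gi, cols] += sign * effect
        truth.de_genes_per_stress[s] = {genes[i] for i in planted_idx}

    u = rng.random(size=x.shape)
    calls = np.where(u < absent_rate, "A", np.where(u < absent_rate + 0.05, "M", "P"))

    bundle = ExpressionBundle(
        matrix=pd.DataFrame(x, index=genes, columns=samples),
        calls=pd.DataFrame(calls, index=genes, columns=samples),
        groups=pd.Series(labels, index=samples, name="condition"),
    )
    return bundle, truth


def gen_network(
    n_nodes: int = 300,
    n_blocks: int = 6,
    p_in: float = 0.3,
    p_out: float = 0.01,
    tlm_fraction: float = 0.15,
    planted: bool = True,
    planted_size: int = 15,
    seed: int = 0,
    stress: str = "ethanol",
    background_de_rate: float = 0.1,
) -> tuple[GeneNetwork, SyntheticTruth]:
    """Generate a stochastic-block-model gene network with TLM/DE annotations.

    With `planted=True`, `planted_size` nodes inside one block are flagged
    both TLM and DE under `stress` — a mutually proximal responsive module.
    The remaining TLM nodes (up to round(tlm_fraction * n_nodes) in total)
    are scattered uniformly. Without planting, the same number of DE-TLM
    flags is assigned uniformly among TLM nodes, independent of block
    structure. Non-TLM nodes are flagged DE at `background_de_rate` in either
    case, so the specificity control has a comparison set.
    """
    _require_positive(n_nodes=n_nodes, n_blocks=n_blocks)
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError(
            f"need p_in > p_out (got p_in={p_in}, p_out={p_out}); "
            "planted proximity would be undefined"
        )
    rng = np.random.default_rng(seed)

    sizes = [n_nodes // n_blocks] * n_blocks
    for i in range(n_nodes % n_blocks):
        sizes[i] += 1
    if planted and planted_size > sizes[0]:
        raise ValueError(
            f"planted_size={planted_size} exceeds block size {sizes[0]}"
        )
    p_matrix = [
        [p_in if i == j else p_out for j in range(n_blocks)] for i in range(n_blocks)
    ]
    g_raw = nx.stochastic_block_model(
        sizes, p_matrix, seed=int(rng.integers(2**31))
    )
    names = {i: f"g{i:05d}" for i in g_raw.nodes}
    g = nx.relabel_nodes(nx.Graph(g_raw.edges), names)
    g.add_nodes_from(names.values())

    n_tlm = max(round(tlm_fraction * n_nodes), planted_size + 2)
    all_nodes = np.array(sorted(names.values()))
    block0 = [names[i] for i in range(sizes[0])]

    truth = SyntheticTruth(seed=seed)
    if planted:
        planted_nodes = set(
            rng.choice(block0, size=planted_size, replace=False)
        )
        rest_pool = np.array(sorted(set(all_nodes) - planted_nodes))
        other_tlm = set(
            rng.choice(rest_pool, size=n_tlm - planted_size, replace=False)
        )
        tlm = planted_nodes | other_tlm
        de_tlm = set(planted_nodes)
        truth.planted_proximal_set = planted_nodes
    else:
        tlm = set(rng.choice(all_nodes, size=n_tlm, replace=False))
        de_tlm = set(rng.choice(sorted(tlm), size=planted_size, replace=False))

    non_tlm = np.array(sorted(set(all_nodes) - tlm))
    de_non_tlm = set(non_tlm[rng.random(len(non_tlm)) < background_de_rate])
    truth.de_genes_per_stress[stress] = de_tlm | de_non_tlm

    net = GeneNetwork(graph=g, tlm=tlm, de_by_stress={stress: de_tlm | de_non_tlm})
    return net, truth


def gen_screen(
    n_mutants: int = 100,
    slope: float = -0.8,
    intercept: float = 40.0,
    sigma: float = 10.0,
    outlier_fraction: float = 0.05,
    outlier_shift: float = 80.0,
    seed: int = 0,
    stress: str = "ethanol",
) -> tuple[ScreenTable, SyntheticTruth]:
    """Generate a mutant screen table with a linear response and planted outliers.

    delta = slope * initial + intercept + N(0, sigma^2); initial lengths are
    uniform on [150, 450] bp of telomeric repeat. Exactly
    round(outlier_fraction * n_mutants) mutants get an extra +/- outlier_shift
    (sign by fair coin). Shifts of at least ~4 sigma are recommended for the
    outliers to be recoverable (not enforced).
    """
    _require_positive(n_mutants=n_mutants)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not (0.0 <= outlier_fraction < 1.0):
        raise ValueError(f"outlier_fraction must be in [0, 1), got {outlier_fraction}")
    rng = np.random.default_rng(seed)

    mutants = [f"mut{i:04d}" for i in range(n_mutants)]
    lo, hi = INITIAL_LENGTH_RANGE
    initial = rng.uniform(lo, hi, size=n_mutants)
    delta = slope * initial + intercept + rng.normal(0.0, sigma, size=n_mutants)

    n_out = round(outlier_fraction * n_mutants)
    out_idx = rng.choice(n_mutants, size=n_out, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_out)
    delta[out_idx] += signs * outlier_shift

    table = ScreenTable.from_columns(
        mutant=mutants, initial=initial, final=initial + delta, stress=stress
    )
    truth = SyntheticTruth(
        seed=seed,
        screen_outliers={mutants[i] for i in out_idx},
        true_slope=slope,
        true_intercept=intercept,
    )
    return table, truth


def gen_lane(
    true_size: float = 1250.0,
    smear_sd: float = 2.0,
    calib_truth=DEFAULT_MARKERS,
    baseline: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 100.0,
    n_points: int = 600,
) -> LaneProfile:
    """Generate a lane profile: a Gaussian band on a flat noisy baseline.

    The band center is the migration position the log-linear model (through
    the two marker bands in `calib_truth`, as (position, size) pairs) assigns
    to `true_size`. `smear_sd` is in migration units. Sizes outside the
    marker-spanned range are rejected — sizing there would extrapolate.
    """
    (p1, s1), (p2, s2) = calib_truth
    calib = calibrate((p1, p2), (s1, s2))
    lo, hi = sorted((s1, s2))
    if not (lo <= true_size <= hi):
        raise ValueError(
            f"true_size={true_size} outside the marker range [{lo}, {hi}]"
        )
    _require_positive(smear_sd=smear_sd, amplitude=amplitude, n_points=n_points)
    rng = np.random.default_rng(seed)

    pmin, pmax = sorted((p1, p2))
    margin = 0.1 * (pmax - pmin)
    positions = np.linspace(pmin - margin, pmax + margin, n_points)
    center = float(calib.position_of(true_size))
    signal = amplitude * np.exp(-((positions - center) ** 2) / (2.0 * smear_sd**2))
    intensities = signal + baseline
    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, size=n_points)
    return LaneProfile(
        positions=positions,
        intensities=np.clip(intensities, 0.0, None),
        marker_positions=(p1, p2),
        marker_sizes=(s1, s2),
    )


def gen_chip_counts(
    true_fold: float = 0.5,
    control_enrichment: float = 2.0,
    n_replicates: int = 3,
    cv: float = 0.1,
    seed: int = 0,
    stress: str = "ethanol",
) -> tuple[list[ChipMeasurement], list[ChipMeasurement]]:
    """Generate ChIP quadruples for a stress and a control condition.

    The control condition has telomere fold enrichment `control_enrichment`;
    the stress condition has `control_enrichment * true_fold`, so the relative
    change recovers `true_fold` (0.5 = two-fold depletion). Each of the four
    quantities carries independent lognormal noise with coefficient of
    variation ~`cv`.
    """
    _require_positive(
        true_fold=true_fold, control_enrichment=control_enrichment,
        n_replicates=n_replicates,
    )
    rng = np.random.default_rng(seed)
    s = np.sqrt(np.log1p(cv**2))  # lognormal sigma for the given CV

    def make(condition: str, enrichment: float) -> list[ChipMeasurement]:
        out = []
        for rep in range(1, n_replicates + 1):
            aro_ip, tel_input, aro_input = np.exp(rng.normal(0.0, s, size=3))
            tel_ip = enrichment * aro_ip * (tel_input / aro_input) * np.exp(
                rng.normal(0.0, s)
            )
            out.append(
                ChipMeasurement(
                    tel_ip=float(tel_ip),
                    aro_ip=float(aro_ip),
                    tel_input=float(tel_input),
                    aro_input=float(aro_input),
                    condition=condition,
                    replicate=rep,
                )
            )
        return out

    stress_meas = make(stress, control_enrichment * true_fold)
    control_meas = make("control", control_enrichment)
    return stress_meas, control_meas
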