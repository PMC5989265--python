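"""Seeded simulators for reference atlases, junction counts and queries.

The generator emulates a nine-time-point developing-cortex reference
(E14.5 .. 21mo) with a module-structured splicing program:

* M1 exons switch late (midpoints between P7 and P15), M2 exons switch
  early (around birth); each splits into + (rising) and − (mirrored,
  falling) members.
* M3/M4 exons follow a sum of an early and a late sigmoid of opposite
  sign, producing non-monotonic trajectories from two independent
  opposite-direction regulatory events.
* null exons are developmentally flat.

Observed Ψ adds two noise layers: truncated-normal (reflected into
[0, 1]) biological noise on the trajectory, then binomial junction-read
sampling at a negative-binomially distributed per-cell coverage.
Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    CORTEX_STAGE_MAP,
    CORTEX_TIMEPOINTS,
    ExonCatalog,
    GeneSetCollection,
    PsiMatrix,
    ReferenceAtlas,
    SpliceCounts,
)
from .psi import estimate_psi
from .timing import TimeAxis, sigmoid

__all__ = [
    "DEFAULT_MODULE_MIX",
    "SimTruth",
    "simulate_reference",
    "simulate_query",
    "simulate_sensory_query",
    "simulate_gene_sets",
    "simulate_sequences",
]

# M1 + M2 dominate the developmental program (~3/4 of regulated exons);
# the non-monotonic M3/M4 modules and unregulated exons make up the rest.
DEFAULT_MODULE_MIX: dict[str, float] = {
    "M1": 0.40,
    "M2": 0.34,
    "M3": 0.08,
    "M4": 0.08,
    "null": 0.10,
}


@dataclass
class SimTruth:
    """Ground truth of one simulated reference."""

    params: pd.DataFrame  # per exon: module, sign, gene_id, a, k, b, m, m2, b2
    stage_labels: list[str]
    axis: TimeAxis
    trajectories: pd.DataFrame  # noise-free Ψ, exon × stage
    stage_map: dict[str, int] = field(default_factory=lambda: dict(CORTEX_STAGE_MAP))

    @property
    def exon_ids(self) -> pd.Index:
        return self.params.index

    def module_of(self) -> pd.Series:
        """Signed module label per exon (M1+, M1-, M2+, M2-, M3, M4, null)."""
        lab = self.params["module"].copy()
        signed = self.params["module"].isin(["M1", "M2"])
        lab[signed] = self.params.loc[signed, "module"] + self.params.loc[
            signed, "sign"
        ]
        return lab

    def eval_at(self, t: float) -> pd.Series:
        """Noise-free Ψ of every exon at log10 pc-day time ``t``."""
        p = self.params
        base = sigmoid(t, p["a"].to_numpy(), p["k"].to_numpy(),
                       p["b"].to_numpy(), p["m"].to_numpy())
        two = p["m2"].notna().to_numpy()
        if two.any():
            second = (p.loc[two, "k"] - p.loc[two, "a"]).to_numpy() * (
                1.0 / (1.0 + np.exp(-p.loc[two, "b2"].to_numpy()
                                    * (t - p.loc[two, "m2"].to_numpy())))
            )
            base = base.astype(float)
            base[two] = np.clip(base[two] - second, 0.0, 1.0)
        return pd.Series(base, index=p.index)

    def catalog(self) -> ExonCatalog:
        """Synthetic BED-style exon catalog consistent with the truth."""
        n = len(self.params)
        table = pd.DataFrame(
            {
                "gene_id": self.params["gene_id"],
                "chrom": "chr1",
                "start": 1000 * np.arange(n) + 100,
                "end": 1000 * np.arange(n) + 200,
                "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
                "novelty": "known",
            },
            index=self.params.index,
        )
        return ExonCatalog(table)

    def atlas(self, estimated_psi: PsiMatrix | None = None) -> ReferenceAtlas:
        """Reference atlas from the estimated (or noise-free) Ψ matrix."""
        psi = estimated_psi if estimated_psi is not None else PsiMatrix(
            self.trajectories.copy()
        )
        return ReferenceAtlas(psi.complete_rows(), dict(self.stage_map))


def _reflect01(x: np.ndarray) -> np.ndarray:
    """Reflect values into [0, 1] (truncated-normal via reflection)."""
    x = np.mod(x, 2.0)
    return np.where(x > 1.0, 2.0 - x, x)


def _draw_params(rng: np.random.Generator, modules: np.ndarray,
                 signs: np.ndarray, axis: TimeAxis) -> pd.DataFrame:
    t = dict(zip(axis.labels, axis.t))
    n = len(modules)
    a = rng.uniform(0.05, 0.25, n)
    k = rng.uniform(0.75, 0.95, n)
    # developmental switches are sharp: 10-90% completion within
    # ~0.12-0.24 log10 pc-days (e.g., E16.5 to P7 around birth)
    bmag = rng.uniform(18.0, 36.0, n)
    b = np.where(signs == "+", bmag, -bmag)
    m = np.empty(n)
    m2 = np.full(n, np.nan)
    b2 = np.full(n, np.nan)
    for mod, lo, hi in (
        ("M2", t["P0"] - 0.03, t["P0"] + 0.03),      # early: around birth
        ("M1", t["P7"] + 0.02, t["P15"] - 0.01),     # late: P7-P15
    ):
        sel = modules == mod
        m[sel] = rng.uniform(lo, hi, sel.sum())
    for mod, m_early, m_late in (
        ("M3", t["P0"], t["P15"]),
        ("M4", t["P0"], t["P7"]),
    ):
        sel = modules == mod
        m[sel] = rng.normal(m_early, 0.02, sel.sum())
        m2[sel] = rng.normal(m_late, 0.02, sel.sum())
        b2[sel] = rng.uniform(18.0, 36.0, sel.sum())
        b[sel] = np.abs(b[sel])  # first switch rises, second falls
    nullsel = modules == "null"
    if nullsel.any():
        flat = rng.uniform(0.2, 0.8, nullsel.sum())
        a[nullsel] = flat
        k[nullsel] = flat
        b[nullsel] = 0.0
        m[nullsel] = t["P0"]
    return pd.DataFrame(
        {"module": modules, "sign": signs, "a": a, "k": k, "b": b,
         "m": m, "m2": m2, "b2": b2}
    )


def simulate_reference(
    n_exons: int = 1000,
    stages: list[str] | None = None,
    coverage_mean: float = 100.0,
    noise_sd: float = 0.05,
    module_mix: dict[str, float] | None = None,
    seed: int = 0,
    coverage_dispersion: float = 10.0,
    exons_per_gene: int = 1,
) -> tuple[SpliceCounts, PsiMatrix, SimTruth]:
    """Simulate a developmental reference with planted splicing modules.

    Returns junction counts, the Ψ matrix estimated from them with the
    default coverage/SD filters, and the generating truth.
    """
    if n_exons < 100:
        raise ValueError("n_exons must be >= 100")
    stages = list(stages) if stages is not None else list(CORTEX_TIMEPOINTS)
    mix = dict(module_mix) if module_mix is not None else dict(DEFAULT_MODULE_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"module_mix must sum to 1, got {sum(mix.values())}")
    rng = np.random.default_rng(seed)
    axis = TimeAxis.from_labels(stages)

    modules = rng.choice(list(mix), size=n_exons, p=list(mix.values()))
    signs = np.where(rng.random(n_exons) < 0.5, "+", "-")
    signs[np.isin(modules, ["M3", "M4", "null"])] = ""
    params = _draw_params(rng, modules, signs, axis)
    params.index = pd.Index([f"ex{i:05d}" for i in range(n_exons)], name="exon_id")
    params["gene_id"] = [
        f"g{i // max(exons_per_gene, 1):05d}" for i in range(n_exons)
    ]

    truth = SimTruth(params=params, stage_labels=stages, axis=axis,
                     trajectories=pd.DataFrame(index=params.index))
    clean = pd.DataFrame(
        {lb: truth.eval_at(tv) for lb, tv in zip(stages, axis.t)}
    )
    truth.trajectories = clean

    noisy = _reflect01(
        clean.to_numpy() + rng.normal(0.0, noise_sd, clean.shape)
    ) if noise_sd > 0 else clean.to_numpy()
    # per-cell coverage: negative binomial around the mean junction depth
    p_nb = coverage_dispersion / (coverage_dispersion + coverage_mean)
    cov = rng.negative_binomial(coverage_dispersion, p_nb, clean.shape)
    incl = rng.binomial(cov, noisy)
    counts = SpliceCounts(
        inc=pd.DataFrame(2 * incl, index=params.index, columns=stages),
        skip=pd.DataFrame(cov - incl, index=params.index, columns=stages),
    )
    psi = estimate_psi(counts)
    return counts, psi, truth


def simulate_query(
    truth: SimTruth,
    age: str,
    coverage_mean: float | None = 100.0,
    noise_sd: float = 0.05,
    missing_frac: float = 0.0,
    seed: int = 0,
) -> tuple[pd.Series, int]:
    """Simulate one query sample at an age within the atlas range.

    Returns the observed Ψ vector and the true stage (stage of the
    nearest reference age). ``coverage_mean=None`` skips read sampling.
    """
    from .timing import to_log10_pcdays

    rng = np.random.default_rng(seed)
    t = to_log10_pcdays(age)
    if not (truth.axis.t.min() - 1e-9 <= t <= truth.axis.t.max() + 1e-9):
        raise ValueError(f"age {age!r} outside the atlas range")
    clean = truth.eval_at(t).to_numpy()
    obs = _reflect01(clean + rng.normal(0.0, noise_sd, clean.shape)) \
        if noise_sd > 0 else clean.copy()
    if coverage_mean:
        cov = np.maximum(
            rng.poisson(coverage_mean, obs.shape), 1
        )
        obs = rng.binomial(cov, obs) / cov
    if missing_frac > 0:
        obs[rng.random(obs.shape) < missing_frac] = np.nan
    nearest = truth.stage_labels[int(np.argmin(np.abs(truth.axis.t - t)))]
    return pd.Series(obs, index=truth.exon_ids), truth.stage_map[nearest]


def simulate_sensory_query(
    truth: SimTruth,
    seed: int = 0,
    noise_sd: float = 0.02,
) -> tuple[pd.Series, dict[str, str]]:
    """Simulate a sensory-neuron-like sample with a dissociated program.

    Early-switch (M2) exons are frozen at their embryonic (first
    time point) values while late-switch (M1) exons sit at their adult
    (last time point) values — the hallmark of mature non-CNS neurons
    that never executed the early switch. Returns the query and the
    expected qualitative pattern per module subset.
    """
    rng = np.random.default_rng(seed)
    first = truth.trajectories.iloc[:, 0]
    last = truth.trajectories.iloc[:, -1]
    obs = last.copy()
    is_m2 = (truth.params["module"] == "M2").to_numpy()
    obs[is_m2] = first[is_m2]
    vals = _reflect01(obs.to_numpy() + rng.normal(0.0, noise_sd, len(obs))) \
        if noise_sd > 0 else obs.to_numpy()
    expected = {"M2": "immature (stage <= 2)", "M1": "mature (stage >= 5)"}
    return pd.Series(vals, index=truth.exon_ids), expected


def simulate_gene_sets(
    truth: SimTruth,
    n_terms: int = 100,
    planted: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    term_size_range: tuple[int, int] = (10, 50),
) -> tuple[GeneSetCollection, dict[str, tuple[int, int]]]:
    """Simulate gene sets over the truth's genes.

    Background terms draw genes uniformly; each ``planted`` term
    (name -> (start_rank, end_rank), 1-based inclusive over the true
    switch-time ranking of M1/M2 exons) concentrates its genes in that
    rank interval.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(set(truth.params["gene_id"]))
    sets: dict[str, set[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        size = min(size, len(genes))
        sets[f"T{i:04d}"] = set(rng.choice(genes, size=size, replace=False))
    planted = dict(planted or {})
    if planted:
        switching = truth.params[truth.params["module"].isin(["M1", "M2"])]
        ranked_genes = switching.sort_values(
            ["m", "gene_id"], kind="mergesort"
        )["gene_id"].tolist()
        for term, (lo, hi) in planted.items():
            sets[term] = set(ranked_genes[lo - 1: hi])
    return GeneSetCollection(sets), planted


def simulate_sequences(
    n_fg: int,
    n_bg: int,
    length: int = 200,
    motif: str | None = None,
    fg_motif_frac: float = 0.8,
    bg_motif_frac: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Random intronic-like sequences with an optionally planted motif."""
    rng = np.random.default_rng(seed)

    def _draw(n, prefix, frac):
        seqs = {}
        for i in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            if motif and rng.random() < frac:
                pos = int(rng.integers(0, length - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
            seqs[f"{prefix}{i:04d}"] = seq
        return seqs

    return _draw(n_fg, "fg", fg_motif_frac), _draw(n_bg, "bg", bg_motif_frac)
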