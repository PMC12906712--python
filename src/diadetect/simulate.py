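"""Synthetic DIA-NN reports with known ground truth.

Generates a long-format precursor report, sample metadata and a
behaviour table with the statistical structure the presence/absence
analysis assumes, so the whole pipeline is testable without any raw MS
data, and doubles as the Monte-Carlo engine for validating the exact
power calculations.

The generative model uses two layers of missingness:

1. a Bernoulli detection layer per protein × sample with group-specific
   probabilities — this layer is the *contractual* detection rate that
   the exact power module reasons about;
2. left-censoring of precursor log2 intensities at a limit of detection
   (LOD), giving the missing-not-at-random character of real DIA data
   on top of the Bernoulli layer.

Precursor log2 intensity = protein mean + per-precursor offset +
Gaussian noise; rows below the LOD are not emitted.  A configurable
fraction of rows receives q-values above the 0.01 acceptance threshold
so the filters are exercised.  All randomness flows from one seeded
generator: identical seeds give byte-identical output files.

Default shape mirrors the reference study: 9 runs (4 dependent, 5
non-dependent; 5 female, 4 male), ~300–350 proteins per run with about
five times as many precursors, plus contaminant proteins (keratins,
hemoglobin) carrying accessions from the bundled synthetic cRAP FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

AMINO_ACIDS = np.array(list("ACDEFGHILMNPSTVWY"))  # no K/R except at the C-terminus

#: Accessions of the synthetic contaminant FASTA (keratins, hemoglobin,
#: trypsin, BSA — the classic cRAP inhabitants), labelled _SYN because the
#: sequences are generated, not the real cRAP entries.
CRAP_ACCESSIONS = (
    "K2C1_SYN",
    "K1C10_SYN",
    "K2C5_SYN",
    "HBA_SYN",
    "HBB_SYN",
    "TRYP_SYN",
    "ALBU_SYN",
)


@dataclass(frozen=True)
class ProteinClassSpec:
    """One protein class: how many, how detectable, how abundant."""

    label: str
    n_proteins: int
    p_detect_dep: float
    p_detect_nondep: float
    mean_log2_intensity: float = 17.0
    sd_log2: float = 1.2
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_detect_dep <= 1.0 and 0.0 <= self.p_detect_nondep <= 1.0):
            raise ValueError("detection probabilities must be in [0, 1]")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")


def default_classes() -> tuple[ProteinClassSpec, ...]:
    """The default class table: dependence markers, control markers,
    shared background, and contaminants."""
    return (
        ProteinClassSpec("dep_marker", 60, 0.90, 0.05, mean_log2_intensity=16.5),
        ProteinClassSpec("nondep_marker", 30, 0.05, 0.90, mean_log2_intensity=16.5),
        ProteinClassSpec("shared", 300, 0.95, 0.95, mean_log2_intensity=18.5, sd_log2=1.5),
        ProteinClassSpec("contaminant", 7, 0.90, 0.90, mean_log2_intensity=20.5,
                         sd_log2=1.0, is_contaminant=True),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative model for a synthetic DIA-NN report.

    ``precursor_mean`` is the mean precursors per protein
    (1 + Poisson(precursor_mean − 1)); ``lod_log2`` the left-censoring
    limit; ``q_value_mixture`` the fraction of rows drawn with q-values
    above 0.01 so the ≤0.01 filters have something to remove.
    """

    seed: int = 0
    n_dep: int = 4
    n_nondep: int = 5
    classes: tuple[ProteinClassSpec, ...] = field(default_factory=default_classes)
    precursor_mean: float = 5.0
    precursor_offset_sd: float = 1.0
    noise_sd: float = 0.4
    lod_log2: float = 12.0
    q_value_mixture: float = 0.05
    bal_range: tuple[float, float] = (150.0, 250.0)

    def __post_init__(self) -> None:
        if self.n_dep < 1 or self.n_nondep < 1:
            raise ValueError("both groups need >= 1 run")
        if not 0.0 <= self.q_value_mixture < 1.0:
            raise ValueError("q_value_mixture must be in [0, 1)")
        if self.precursor_mean < 1.0:
            raise ValueError("precursor_mean must be >= 1")


@dataclass
class SyntheticBundle:
    """A generated report plus its ground truth."""

    report: pd.DataFrame            # canonical precursor records
    metadata: pd.DataFrame          # run_id, animal_id, group, sex
    proteins: pd.DataFrame          # protein_group, label, is_contaminant
    detection_truth: pd.DataFrame   # Bernoulli layer, proteins × runs (bool)
    protein_log2: pd.DataFrame      # true protein log2 mean where detected, else NaN
    n_rows: int                     # emitted report rows (post-censoring)
    config: SyntheticConfig


def _make_metadata(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = []
    # alternate sexes starting F in each group: at the default 4 Dep/5 NonDep
    # this yields the study shape of 5 females and 4 males
    for i in range(cfg.n_dep):
        rows.append((f"D{i + 1}", f"dep_{i + 1:02d}", "Dep", "F" if i % 2 == 0 else "M"))
    for i in range(cfg.n_nondep):
        rows.append((f"N{i + 1}", f"nondep_{i + 1:02d}", "NonDep", "F" if i % 2 == 0 else "M"))
    return pd.DataFrame(rows, columns=["run_id", "animal_id", "group", "sex"])


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 15))
    body = "".join(rng.choice(AMINO_ACIDS, size=length))
    return body + ("K" if rng.random() < 0.5 else "R")


def _draw_q(rng: np.random.Generator, size: int, mixture: float) -> np.ndarray:
    """q-value mixture: mostly ≤ 0.01, a ``mixture`` fraction in (0.01, 0.5]."""
    good = rng.uniform(0.0, 0.01, size=size)
    bad = rng.uniform(0.011, 0.5, size=size)
    take_bad = rng.random(size) < mixture
    return np.where(take_bad, bad, good)


def generate_report(cfg: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate a synthetic DIA-NN report, metadata, and ground truth."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    meta = _make_metadata(cfg)
    runs = list(meta["run_id"])
    is_dep = (meta["group"] == "Dep").to_numpy()

    protein_rows = []
    crap_cycle = list(CRAP_ACCESSIONS)
    counters: dict[str, int] = {}
    for cls in cfg.classes:
        for _ in range(cls.n_proteins):
            idx = counters.get(cls.label, 0)
            counters[cls.label] = idx + 1
            if cls.is_contaminant:
                acc = crap_cycle[idx % len(crap_cycle)]
                if idx >= len(crap_cycle):
                    acc = f"{acc}{idx // len(crap_cycle)}"
            else:
                acc = f"{cls.label.upper()}{idx:04d}"
            protein_rows.append((acc, cls.label, cls.is_contaminant))
    proteins = pd.DataFrame(protein_rows, columns=["protein_group", "label", "is_contaminant"])
    class_by_label = {c.label: c for c in cfg.classes}

    report_rows: list[tuple] = []
    det_truth = np.zeros((len(proteins), len(runs)), dtype=bool)
    true_log2 = np.full((len(proteins), len(runs)), np.nan)
    for p_idx, prot in enumerate(proteins.itertuples()):
        cls = class_by_label[prot.label]
        n_prec = 1 + int(rng.poisson(cfg.precursor_mean - 1.0))
        peptides = [_random_peptide(rng) for _ in range(n_prec)]
        charges = rng.integers(2, 4, size=n_prec)
        offsets = rng.normal(0.0, cfg.precursor_offset_sd, size=n_prec)
        protein_means = cls.mean_log2_intensity + rng.normal(0.0, cls.sd_log2, size=len(runs))
        p_vec = np.where(is_dep, cls.p_detect_dep, cls.p_detect_nondep)
        detected = rng.random(len(runs)) < p_vec
        det_truth[p_idx] = detected
        global_q = _draw_q(rng, 1, cfg.q_value_mixture / 5.0)[0]
        for s_idx, run in enumerate(runs):
            if not detected[s_idx]:
                continue
            true_log2[p_idx, s_idx] = protein_means[s_idx]
            noise = rng.normal(0.0, cfg.noise_sd, size=n_prec)
            intensities = protein_means[s_idx] + offsets + noise
            qs = _draw_q(rng, n_prec, cfg.q_value_mixture)
            pg_q = _draw_q(rng, 1, cfg.q_value_mixture / 2.0)[0]
            for j in range(n_prec):
                if intensities[j] <= cfg.lod_log2:
                    continue  # left-censored: row never emitted
                report_rows.append(
                    (
                        run,
                        prot.protein_group,
                        prot.label.upper(),
                        f"{peptides[j]}{charges[j]}",
                        peptides[j],
                        int(charges[j]),
                        qs[j],
                        pg_q,
                        global_q,
                        global_q,
                        float(np.exp2(intensities[j])),
                    )
                )

    report = pd.DataFrame(
        report_rows,
        columns=[
            "run_id", "protein_group", "genes", "precursor_id", "modified_sequence",
            "charge", "q_value", "pg_q_value", "global_q_value", "global_pg_q_value",
            "quantity",
        ],
    )
    return SyntheticBundle(
        report=report,
        metadata=meta,
        proteins=proteins,
        detection_truth=pd.DataFrame(det_truth, index=proteins["protein_group"], columns=runs),
        protein_log2=pd.DataFrame(true_log2, index=proteins["protein_group"], columns=runs),
        n_rows=len(report),
        config=cfg,
    )


def generate_behavior(
    cfg: SyntheticConfig,
    bundle: SyntheticBundle,
    planted_correlation: tuple[str, str, float] | None = None,
) -> pd.DataFrame:
    """Per-animal drinking and blood-alcohol behaviour table.

    Dependent animals escalate (escalation ratio ~ N(1.8, 0.3));
    non-dependent animals do not (~ N(1.0, 0.1)).  Per-cycle blood
    alcohol levels for dependent animals are drawn within
    ``cfg.bal_range`` (the 150–250 mg/dL target window of the vapour
    paradigm); non-dependent animals, exposed only to air, get 0.

    ``planted_correlation = (protein_group, metric, r)`` rewrites the
    metric column ("cie_intake" or "escalation_ratio") as a linear
    function of the protein's true log2 abundance plus noise scaled for
    correlation ``r`` (r = ±1 → noiseless).
    """
    rng = np.random.default_rng(cfg.seed + 1)  # independent stream from the report
    meta = bundle.metadata
    rows = []
    for animal in meta.itertuples():
        baseline = max(0.5, rng.normal(2.5, 0.5))
        if animal.group == "Dep":
            escalation = max(1.05, rng.normal(1.8, 0.3))
            lo, hi = cfg.bal_range
            margin = 0.1 * (hi - lo)
            bal = rng.uniform(lo + margin, hi - margin, size=6)
        else:
            escalation = max(0.5, rng.normal(1.0, 0.1))
            bal = np.zeros(6)
        rows.append(
            {
                "animal_id": animal.animal_id,
                "run_id": animal.run_id,
                "group": animal.group,
                "sex": animal.sex,
                "baseline_intake": round(baseline, 3),
                "cie_intake": round(baseline * escalation, 3),
                "escalation_ratio": round(escalation, 3),
                **{f"bal_cycle{i + 1}": round(float(b), 1) for i, b in enumerate(bal)},
            }
        )
    behavior = pd.DataFrame(rows)
    behavior["escalation_ratio"] = behavior["cie_intake"] / behavior["baseline_intake"]

    if planted_correlation is not None:
        protein, metric, r = planted_correlation
        if metric not in ("cie_intake", "escalation_ratio"):
            raise ValueError(f"cannot plant correlation on {metric!r}")
        x = bundle.protein_log2.loc[protein, behavior["run_id"]].to_numpy(dtype=float)
        x = np.where(np.isnan(x), np.nanmean(x), x)
        z = (x - x.mean()) / (x.std() or 1.0)
        noise = rng.normal(0.0, 1.0, size=len(z))
        noise = (noise - noise.mean()) / (noise.std() or 1.0)
        # remove the component of noise along z so the sample correlation is exact
        noise = noise - z * np.dot(noise, z) / np.dot(z, z)
        sd = noise.std() or 1.0
        signal = np.sign(r) * abs(r) * z + np.sqrt(max(0.0, 1 - r * r)) * noise / sd
        behavior[metric] = 2.0 + 0.5 * signal
        if metric == "cie_intake":
            behavior["escalation_ratio"] = behavior["cie_intake"] / behavior["baseline_intake"]
        else:  # keep escalation_ratio = cie_intake / baseline_intake consistent
            behavior["cie_intake"] = behavior["baseline_intake"] * behavior["escalation_ratio"]
    return behavior


def crap_fasta_text(rng_seed: int = 12345) -> str:
    """Synthetic cRAP-style contaminant FASTA (generated sequences)."""
    rng = np.random.default_rng(rng_seed)
    chunks = []
    names = {
        "K2C1_SYN": "Keratin type II cytoskeletal 1 (synthetic)",
        "K1C10_SYN": "Keratin type I cytoskeletal 10 (synthetic)",
        "K2C5_SYN": "Keratin type II cytoskeletal 5 (synthetic)",
        "HBA_SYN": "Hemoglobin subunit alpha (synthetic)",
        "HBB_SYN": "Hemoglobin subunit beta (synthetic)",
        "TRYP_SYN": "Trypsin (synthetic)",
        "ALBU_SYN": "Serum albumin (synthetic)",
    }
    for acc in CRAP_ACCESSIONS:
        seq = "M" + "".join(rng.choice(AMINO_ACIDS, size=120))
        chunks.append(f">sp|{acc}|{acc} {names[acc]}\n{seq}\n")
    return "".join(chunks)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write report TSV (DIA-NN dialect), metadata/behavior CSVs, truth TSV
    and the contaminant FASTA; returns the paths."""
    from diadetect.diann_io import write_report

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out_dir / "report.tsv",
        "metadata": out_dir / "metadata.csv",
        "behavior": out_dir / "behavior.csv",
        "truth": out_dir / "truth.tsv",
        "crap_fasta": out_dir / "crap_synthetic.fasta",
    }
    write_report(bundle.report, paths["report"])
    bundle.metadata.to_csv(paths["metadata"], index=False)
    behavior = generate_behavior(bundle.config, bundle)
    behavior.to_csv(paths["behavior"], index=False)
    truth = bundle.proteins.merge(
        bundle.detection_truth.astype(int).reset_index(), on="protein_group"
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["crap_fasta"].write_text(crap_fasta_text())
    return paths


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of a config with a different seed."""
    return replace(cfg, seed=seed)
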