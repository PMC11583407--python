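"""Synthetic multi-array DNA methylation datasets with known ground truth.

Emulates a cohort measured on successive Illumina array generations (450K /
EPICv1 / EPICv2 style): the same donors assayed on every array, a couple of
technical replicates shared across arrays, per-probe per-array additive
offsets (array bias), a set of CpGs with a true sex effect, SNP fingerprint
probes whose betas cluster by genotype near 0 / 0.5 / 1, and — on the newest
array — a subset of SNP probes whose manifest attributes (probe sequence,
color channel, next base) no longer match the older generations and whose
measured betas carry no genotype signal at all.

Every stochastic choice flows from one :class:`numpy.random.Generator`
seeded by ``SimulationConfig.seed``, so a fixed seed reproduces the dataset
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import json

import numpy as np
import pandas as pd
import yaml

from .clocks import ClockDefinition

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_clock",
    "write_dataset",
    "load_config",
]

_ARRAY_NAMES_3 = ("450K", "EPICv1", "EPICv2")
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic multi-array dataset.

    Defaults mirror the emulated design: 30 donors (15 F / 15 M, ~5 years
    old) measured on 3 array generations, 2 donors duplicated as technical
    replicates on every array, 57 SNP fingerprint probes of which 21 are
    corrupted on the newest array.
    """

    n_samples: int = 30
    n_cpg: int = 2000
    n_snp_probes: int = 57
    n_arrays: int = 3
    overlap_fraction: float = 0.8
    n_shared_replicates: int = 2
    array_bias_sd: float = 0.015   # median |offset| of N(0, sd) ~ 0.0101
    noise_sd: float = 0.01
    n_sex_cpgs: int = 50
    sex_effect_size: float = 0.05
    n_corrupt_snp_probes: int = 21
    clock_sizes: Sequence[int] = (10,)
    seed: int = 0
    # beta-distribution mixture for per-probe mean methylation: most probes
    # sit near 0 or 1, a minority intermediate
    mixture_weights: Sequence[float] = (0.4, 0.4, 0.2)
    mixture_params: Sequence[Sequence[float]] = ((1, 10), (10, 1), (2, 2))
    biological_sd: float = 0.5     # logit-scale person-to-person jitter
    n_replicate_probes: int = 10   # EPICv2-style duplicated probes, newest array
    n_age_probes: int = 10         # CpGs that define the latent age signal
    fixed_array_offsets: Optional[Sequence[float]] = None  # per-array constant

    def validate(self) -> None:
        counts = dict(n_samples=self.n_samples, n_cpg=self.n_cpg,
                      n_snp_probes=self.n_snp_probes, n_arrays=self.n_arrays,
                      n_shared_replicates=self.n_shared_replicates,
                      n_sex_cpgs=self.n_sex_cpgs,
                      n_corrupt_snp_probes=self.n_corrupt_snp_probes,
                      n_replicate_probes=self.n_replicate_probes,
                      n_age_probes=self.n_age_probes)
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_arrays < 2:
            raise ValueError("need at least 2 arrays")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        for name in ("array_bias_sd", "noise_sd", "biological_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_shared_replicates > self.n_samples:
            raise ValueError("n_shared_replicates cannot exceed n_samples")
        if round(self.overlap_fraction * self.n_cpg) < 2:
            raise ValueError("overlap yields fewer than 2 shared CpGs")
        if self.n_snp_probes - self.n_corrupt_snp_probes < 2:
            raise ValueError("fewer than 2 SNP probes survive uncorrupted")
        if self.fixed_array_offsets is not None and \
                len(self.fixed_array_offsets) != self.n_arrays:
            raise ValueError("fixed_array_offsets must list one offset per array")

    def array_names(self) -> list[str]:
        if self.n_arrays == 3:
            return list(_ARRAY_NAMES_3)
        return [f"array{i + 1}" for i in range(self.n_arrays)]


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    true_beta: pd.DataFrame              # donors x cg probes, in [0, 1]
    sample_sex: pd.Series                # donor -> 'F' | 'M'
    sample_age: pd.Series                # donor -> years
    array_offsets: dict                  # array -> Series over cg probes
    sex_effect_probes: pd.Series         # probe -> delta beta (F - M)
    snp_genotypes: pd.DataFrame          # donors x rs probes, expected beta {0,.5,1}
    corrupted_snp_probes: list
    shared_probes: list                  # cg probes present on every array
    age_probes: list
    age_weights: pd.Series
    age_intercept: float
    clock_truth: dict = field(default_factory=dict)  # name -> ClockDefinition


@dataclass
class SyntheticDataset:
    betas: dict        # array name -> DataFrame (probes x positions)
    manifests: dict    # array name -> manifest DataFrame
    samples: dict      # array name -> sample sheet DataFrame
    truth: GroundTruth
    config: SimulationConfig

    def __iter__(self):
        return iter((list(self.betas.values()), list(self.manifests.values()),
                     self.truth))


def _logit(p):
    return np.log(p / (1.0 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _random_seq(rng, k: int = 50) -> str:
    return "".join(rng.choice(_BASES, size=k))


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate beta matrices, manifests and sample sheets for every array."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    arrays = config.array_names()
    newest = arrays[-1]

    cg_ids = [f"cg{i:08d}" for i in range(1, config.n_cpg + 1)]
    rs_ids = [f"rs{i:07d}" for i in range(1, config.n_snp_probes + 1)]
    donors = [f"D{i:03d}" for i in range(1, config.n_samples + 1)]

    # --- sexes and probe partition -------------------------------------
    half = config.n_samples // 2
    sexes = np.array(["F"] * half + ["M"] * (config.n_samples - half))
    rng.shuffle(sexes)
    sample_sex = pd.Series(sexes, index=donors, name="sex")

    n_shared = int(round(config.overlap_fraction * config.n_cpg))
    order = rng.permutation(config.n_cpg)
    shared = [cg_ids[i] for i in sorted(order[:n_shared])]
    remainder = [cg_ids[i] for i in sorted(order[n_shared:])]
    exclusive: dict[str, list[str]] = {a: [] for a in arrays}
    for i, pid in enumerate(remainder):
        exclusive[arrays[i % len(arrays)]].append(pid)

    # --- true methylation ----------------------------------------------
    comp = rng.choice(len(config.mixture_weights), size=config.n_cpg,
                      p=np.asarray(config.mixture_weights, float)
                      / np.sum(config.mixture_weights))
    params = np.asarray(config.mixture_params, float)
    probe_mean = rng.beta(params[comp, 0], params[comp, 1])
    probe_mean = np.clip(probe_mean, 1e-4, 1 - 1e-4)
    jitter = rng.normal(0.0, config.biological_sd,
                        size=(config.n_samples, config.n_cpg))
    true = _sigmoid(_logit(probe_mean)[None, :] + jitter)
    true_beta = pd.DataFrame(true, index=donors, columns=cg_ids)

    # --- sex-effect CpGs -------------------------------------------------
    # Base betas are squashed into (0.2, 0.7) and male/female group means
    # balanced exactly, so the configured delta is the exact group-mean
    # difference and no clipping can disturb it.
    n_sex = min(config.n_sex_cpgs, n_shared)
    sex_probes = list(rng.choice(shared, size=n_sex, replace=False))
    sex_probes.sort()
    is_f = (sample_sex == "F").to_numpy()
    if n_sex and is_f.any() and (~is_f).any():
        base = 0.2 + 0.5 * true_beta[sex_probes].to_numpy()
        overall = base.mean(axis=0, keepdims=True)
        for mask in (is_f, ~is_f):
            base[mask] += overall - base[mask].mean(axis=0, keepdims=True)
        base[is_f] += config.sex_effect_size
        true_beta.loc[:, sex_probes] = base
    sex_effect_probes = pd.Series(config.sex_effect_size, index=sex_probes,
                                  name="delta", dtype=float)

    # --- latent age signal ----------------------------------------------
    n_age = min(config.n_age_probes, max(n_shared - n_sex, 0))
    age_pool = [p for p in shared if p not in set(sex_probes)]
    age_probes = list(rng.choice(age_pool, size=n_age, replace=False)) if n_age else []
    age_probes.sort()
    if age_probes:
        w0 = rng.normal(0.0, 2.0, size=len(age_probes))
        raw = true_beta[age_probes].to_numpy() @ w0
        sd = raw.std(ddof=0)
        scale = 0.5 / sd if sd > 0 else 0.0
        age_weights = pd.Series(w0 * scale, index=age_probes, name="weight")
        age_intercept = 5.06 - float(raw.mean()) * scale
        ages = age_intercept + raw * scale
    else:
        age_weights = pd.Series(dtype=float)
        age_intercept = 5.06
        ages = np.full(config.n_samples, 5.06)
    sample_age = pd.Series(ages, index=donors, name="age")

    # --- SNP fingerprints -------------------------------------------------
    maf = rng.uniform(0.2, 0.5, size=config.n_snp_probes)
    geno = rng.binomial(2, maf[None, :],
                        size=(config.n_samples, config.n_snp_probes)) / 2.0
    snp_genotypes = pd.DataFrame(geno, index=donors, columns=rs_ids)
    corrupted = list(rng.choice(rs_ids, size=config.n_corrupt_snp_probes,
                                replace=False))
    corrupted.sort()

    # --- array offsets ----------------------------------------------------
    array_offsets = {}
    for ai, a in enumerate(arrays):
        if config.fixed_array_offsets is not None:
            off = np.full(config.n_cpg, float(config.fixed_array_offsets[ai]))
        else:
            off = rng.normal(0.0, config.array_bias_sd, size=config.n_cpg)
        array_offsets[a] = pd.Series(off, index=cg_ids, name=a)

    # --- manifests --------------------------------------------------------
    probe_attrs = {}
    type1 = rng.random(config.n_cpg) < 0.2
    chrom = rng.integers(1, 23, size=config.n_cpg + config.n_snp_probes)
    pos = rng.integers(1, 2**27, size=config.n_cpg + config.n_snp_probes)
    for i, pid in enumerate(cg_ids):
        if type1[i]:
            probe_attrs[pid] = ("cg", "I", _random_seq(rng),
                                str(rng.choice(["Red", "Grn"])),
                                str(rng.choice(_BASES)),
                                str(chrom[i]), int(pos[i]))
        else:
            probe_attrs[pid] = ("cg", "II", _random_seq(rng), "none", "none",
                                str(chrom[i]), int(pos[i]))
    for j, pid in enumerate(rs_ids):
        i = config.n_cpg + j
        probe_attrs[pid] = ("rs", "I", _random_seq(rng),
                            str(rng.choice(["Red", "Grn"])),
                            str(rng.choice(_BASES)),
                            str(chrom[i]), int(pos[i]))

    # corrupted attribute overrides, newest array only
    corrupt_attrs = {}
    for pid in corrupted:
        cat, dt, seq, chan, nb, c, p = probe_attrs[pid]
        which = rng.random(3) < 0.5
        if not which.any():
            which[rng.integers(3)] = True
        if which[0]:
            seq = _random_seq(rng)
        if which[1]:
            chan = "Grn" if chan == "Red" else "Red"
        if which[2]:
            nb = str(rng.choice(_BASES[_BASES != nb]))
        corrupt_attrs[pid] = (cat, dt, seq, chan, nb, c, p)

    n_dup = min(config.n_replicate_probes, n_shared)
    dup_probes = list(rng.choice(shared, size=n_dup, replace=False)) if n_dup else []
    dup_probes = sorted(dup_probes)

    manifests = {}
    for a in arrays:
        rows = []
        for pid in sorted(shared + exclusive[a]) + rs_ids:
            attrs = probe_attrs[pid]
            if a == newest and pid in corrupt_attrs:
                attrs = corrupt_attrs[pid]
            cat, dt, seq, chan, nb, c, p = attrs
            if a == newest and pid in dup_probes:
                for suffix in ("_BC11", "_TC21"):
                    rows.append((pid + suffix, cat, dt, seq, chan, nb, c, p))
            else:
                rows.append((pid, cat, dt, seq, chan, nb, c, p))
        manifests[a] = pd.DataFrame(
            rows, columns=["IlmnID", "Category", "Infinium_Design_Type",
                           "AlleleA_ProbeSeq", "Color_Channel", "Next_Base",
                           "CHR", "MAPINFO"])

    # --- sample sheets and measured betas ---------------------------------
    rep_donors = donors[:config.n_shared_replicates]
    samples = {}
    betas = {}
    for a in arrays:
        recs = [{"position_id": f"{a}_{d}", "donor_id": d, "array": a,
                 "is_replicate": False} for d in donors]
        recs += [{"position_id": f"{a}_{d}_rep", "donor_id": d, "array": a,
                  "is_replicate": True} for d in rep_donors]
        sheet = pd.DataFrame(recs)
        sheet["sex"] = sample_sex[sheet["donor_id"]].to_numpy()
        sheet["age"] = sample_age[sheet["donor_id"]].to_numpy()
        samples[a] = sheet

        probe_rows = manifests[a]["IlmnID"].tolist()
        base_of = [pr.rsplit("_", 1)[0] if pr.startswith("cg") and "_" in pr else pr
                   for pr in probe_rows]
        cg_rows = [i for i, b in enumerate(base_of) if b.startswith("cg")]
        rs_rows = [i for i, b in enumerate(base_of) if b.startswith("rs")]

        n_pos = len(sheet)
        mat = np.empty((len(probe_rows), n_pos))
        donor_idx = true_beta.index.get_indexer(sheet["donor_id"])

        cg_bases = [base_of[i] for i in cg_rows]
        signal = (true_beta[cg_bases].to_numpy()[donor_idx].T
                  + array_offsets[a][cg_bases].to_numpy()[:, None])
        mat[cg_rows, :] = signal

        rs_bases = [base_of[i] for i in rs_rows]
        mat[rs_rows, :] = snp_genotypes[rs_bases].to_numpy()[donor_idx].T
        if a == newest and corrupted:
            bad_rows = [i for i in rs_rows if base_of[i] in set(corrupted)]
            mat[bad_rows, :] = rng.uniform(0.0, 1.0, size=(len(bad_rows), n_pos))

        if config.noise_sd > 0:
            mat = mat + rng.normal(0.0, config.noise_sd, size=mat.shape)
        np.clip(mat, 0.0, 1.0, out=mat)
        betas[a] = pd.DataFrame(mat, index=probe_rows,
                                columns=sheet["position_id"].tolist())

    truth = GroundTruth(
        true_beta=true_beta, sample_sex=sample_sex, sample_age=sample_age,
        array_offsets=array_offsets, sex_effect_probes=sex_effect_probes,
        snp_genotypes=snp_genotypes, corrupted_snp_probes=corrupted,
        shared_probes=shared, age_probes=age_probes, age_weights=age_weights,
        age_intercept=age_intercept)

    dataset = SyntheticDataset(betas=betas, manifests=manifests,
                               samples=samples, truth=truth, config=config)
    for k in config.clock_sizes:
        name = f"toy_clock_{k}"
        truth.clock_truth[name] = generate_clock(k, truth, name=name)
    return dataset


def generate_clock(n_cpgs: int, truth: GroundTruth,
                   transform: str = "identity",
                   name: str | None = None) -> ClockDefinition:
    """Build a toy clock that reproduces ``truth.sample_age`` from true betas.

    The clock's probe set is the dataset's latent aging CpGs, padded with
    further shared CpGs up to ``n_cpgs``; coefficients are the least-squares
    fit of the (inverse-transformed) ages on the noise-free betas.  Under
    the identity transform the fit is exact by construction whenever the
    probe set covers the aging CpGs (ages are linear in those betas); for
    nonlinear transforms it is a least-squares approximation.  The maximum
    training residual, on the linear-predictor scale, is recorded in
    ``fit_residual``.
    """
    pool = list(truth.age_probes) + [p for p in truth.shared_probes
                                     if p not in set(truth.age_probes)]
    if n_cpgs < 1 or n_cpgs > len(pool):
        raise ValueError(f"n_cpgs must be in [1, {len(pool)}], got {n_cpgs}")
    probes = pool[:n_cpgs]
    B = truth.true_beta[probes].to_numpy()
    n = B.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to fit a clock")
    X = np.column_stack([np.ones(n), B])
    dummy = ClockDefinition(name="_fit", intercept=0.0, weights={"_": 1.0},
                            transform=transform)
    y = dummy.invert_transform(truth.sample_age.to_numpy())
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank == 0:
        raise ValueError("singular design: clock fit is degenerate")
    resid = float(np.max(np.abs(X @ coef - y)))
    return ClockDefinition(
        name=name or f"toy_clock_{n_cpgs}",
        intercept=float(coef[0]),
        weights=dict(zip(probes, coef[1:].astype(float))),
        transform=transform,
        impute_values=dict(zip(probes, B.mean(axis=0).astype(float))),
        fit_residual=resid)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write beta TSVs, manifest CSVs, sample sheets and ground truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for a in dataset.betas:
        dataset.betas[a].to_csv(out / f"beta_{a}.tsv", sep="\t",
                                index_label="probe_id")
        dataset.manifests[a].to_csv(out / f"manifest_{a}.csv", index=False)
        dataset.samples[a].to_csv(out / f"samples_{a}.csv", index=False)
    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    t = dataset.truth
    t.true_beta.to_csv(tdir / "true_beta.csv", index_label="donor_id")
    t.snp_genotypes.to_csv(tdir / "snp_genotypes.csv", index_label="donor_id")
    pd.DataFrame({"donor_id": t.sample_sex.index, "sex": t.sample_sex.values,
                  "age": t.sample_age.values}).to_csv(tdir / "donors.csv",
                                                      index=False)
    pd.DataFrame(t.array_offsets).to_csv(tdir / "array_offsets.csv",
                                         index_label="probe_id")
    meta = {
        "sex_effect_probes": {k: float(v) for k, v in t.sex_effect_probes.items()},
        "corrupted_snp_probes": list(t.corrupted_snp_probes),
        "shared_probes": list(t.shared_probes),
        "age_probes": list(t.age_probes),
        "age_intercept": t.age_intercept,
        "config": asdict(dataset.config),
    }
    meta["config"]["clock_sizes"] = list(dataset.config.clock_sizes)
    with open(tdir / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=list)


def load_config(path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg
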