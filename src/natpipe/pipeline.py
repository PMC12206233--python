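"""End-to-end orchestration: synthesize -> connectomes -> NAT -> scores -> stats.

Each stage is a plain function over in-memory objects; :func:`run_pipeline`
wires them together and writes a plain-text results bundle (tab-separated
tables plus a provenance block) so a run is reproducible from its config
and seed alone. Stages can equally consume precomputed inputs (connectivity
matrices, covariates, diaries, batteries) from text files, which is how
non-synthetic data enter.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .atlas import NETWORK_LEVELS, ROIAtlas, read_atlas, synthetic_atlas
from .attack import mean_nat_table, nat_table
from .behavior import TestBatteryResult, composite_scores, composites_frame, \
    lifetime_pa_from_diary
from .connectome import DENSITY_GRID, ConnectivityMatrix, fisher_connectivity, \
    temporal_snr
from .errors import ConfigurationError, ContractError
from .stats import GLMMSpec, fit_beta_glmm, fit_moderation, johnson_neyman
from .synthetic import CohortConfig, generate_batteries, generate_cohort, \
    generate_diary, generate_timeseries, profiles_frame

log = logging.getLogger("natpipe")

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class RunConfig:
    """Settings of one pipeline run.

    In synthetic mode (default) the cohort generator provides every input;
    otherwise ``matrices_dir`` (one dense text matrix per participant),
    ``covariates_path``, ``diaries_path`` and ``batteries_path`` point at
    precomputed data.
    """

    out_dir: str = "results"
    synthetic: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    atlas_path: str | None = None
    matrices_dir: str | None = None
    covariates_path: str | None = None
    diaries_path: str | None = None
    batteries_path: str | None = None
    directions_path: str | None = None
    networks: tuple = NETWORK_LEVELS
    densities: tuple = DENSITY_GRID
    attack_mode: str = "adaptive"       # or "static"
    edge_rank: str = "signed"           # or "abs"
    composite_mode: str = "sum"         # or "mean"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.networks) - set(NETWORK_LEVELS)
        if unknown:
            raise ConfigurationError(f"unknown networks: {sorted(unknown)}")
        if not all(0 < d <= 1 for d in self.densities):
            raise ConfigurationError("densities must lie in (0, 1]")
        if self.attack_mode not in ("adaptive", "static"):
            raise ConfigurationError(f"unknown attack mode {self.attack_mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not self.synthetic and self.matrices_dir is None:
            raise ConfigurationError(
                "non-synthetic runs require matrices_dir with connectivity matrices"
            )
        if self.seed != self.cohort.seed:
            object.__setattr__(self, "cohort",
                               CohortConfig(**{**asdict(self.cohort),
                                               "seed": self.seed}))


@dataclass
class ResultsBundle:
    """All tables produced by a run, plus the provenance block."""

    config: RunConfig
    profiles: pd.DataFrame
    nat: pd.DataFrame
    mean_nat: pd.DataFrame
    composites: pd.DataFrame
    pa: pd.Series
    tsnr: pd.DataFrame | None
    glmm: dict
    glmm_table: pd.DataFrame
    moderation: dict
    moderation_table: pd.DataFrame
    jn: dict
    jn_table: pd.DataFrame
    provenance: dict
    warnings: list = field(default_factory=list)
    complete: bool = True


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    import scipy
    import statsmodels
    return {
        "config": asdict(config),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "natpipe": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig):
    """Synthesize atlas, cohort, ROI time series and activity diaries."""
    t0 = time.perf_counter()
    atlas = read_atlas(config.atlas_path) if config.atlas_path else synthetic_atlas()
    profiles = generate_cohort(config.cohort)
    series = {p.id: generate_timeseries(p, atlas, config.cohort)
              for p in profiles}
    diaries = pd.concat(
        [generate_diary(p, config.cohort) for p in profiles], ignore_index=True
    )
    log.info("simulate: %d participants, %d ROIs [%.1fs]",
             len(profiles), atlas.n_rois, time.perf_counter() - t0)
    return atlas, profiles, series, diaries


def connect_stage(series: dict, atlas: ROIAtlas):
    """Fisher-z connectivity matrices and the per-scan tSNR summary."""
    t0 = time.perf_counter()
    matrices, tsnr_rows = {}, []
    for pid, ts in series.items():
        matrices[pid] = fisher_connectivity(ts, roi_ids=atlas.roi_ids)
        snr = temporal_snr(ts)
        tsnr_rows.append((pid, snr.scan_mean, snr.n_undefined))
    tsnr = pd.DataFrame(tsnr_rows, columns=["participant", "tsnr_mean",
                                            "n_undefined_rois"])
    log.info("connect: %d matrices [%.1fs]", len(matrices),
             time.perf_counter() - t0)
    return matrices, tsnr


def attack_stage(matrices: dict, atlas: ROIAtlas, config: RunConfig) -> pd.DataFrame:
    """NAT long table over participants x networks x densities."""
    t0 = time.perf_counter()
    nat = nat_table(matrices, atlas, networks=config.networks,
                    densities=config.densities, rank=config.edge_rank,
                    mode=config.attack_mode)
    log.info("attack: %d NAT records [%.1fs]", len(nat),
             time.perf_counter() - t0)
    return nat


def score_stage(profiles, nat: pd.DataFrame, diaries: pd.DataFrame,
                config: RunConfig, batteries=None):
    """Mean NAT, diary-based PA, test batteries and composite scores.

    In synthetic mode the batteries are generated here (they depend on the
    realized NAT); precomputed batteries may be passed instead.
    """
    t0 = time.perf_counter()
    wide = mean_nat_table(nat)
    behavior_net = "global" if "global" in config.networks else config.networks[0]
    nat_mean = wide[f"nat_{behavior_net}"]
    if batteries is None:
        # HC behavior carries no NAT coupling; the placeholder value is inert
        nat_lookup = {p.id: nat_mean.get(p.id, 0.5) for p in profiles}
        batteries = generate_batteries(profiles, nat_lookup, config.cohort)
    pa = lifetime_pa_from_diary(diaries)
    by_group = {"PD": [], "HC": []}
    groups = (profiles_frame(profiles) if not isinstance(profiles, pd.DataFrame)
              else profiles).set_index("participant")["group"]
    for b in batteries:
        by_group[groups[b.participant]].append(b)
    comps = composite_scores(by_group["PD"], by_group["HC"],
                             mode=config.composite_mode)
    comp_df = composites_frame(comps)
    log.info("score: %d composites [%.1fs]", len(comp_df),
             time.perf_counter() - t0)
    return wide, pa, batteries, comp_df


def glmm_frame(nat: pd.DataFrame, profiles_df: pd.DataFrame,
               network: str) -> pd.DataFrame:
    """Long model frame for one network's beta GLMM (PD participants)."""
    pd_rows = profiles_df[profiles_df["group"] == "PD"]
    sub = nat[nat["network"] == network]
    return sub.merge(pd_rows, on="participant", how="inner")


def moderation_frame(profiles_df: pd.DataFrame, mean_nat: pd.DataFrame,
                     composites: pd.DataFrame, pa: pd.Series,
                     network: str) -> pd.DataFrame:
    """Per-participant frame for one network's moderation models (PD only)."""
    df = profiles_df[profiles_df["group"] == "PD"].set_index("participant").copy()
    df["nat"] = mean_nat[f"nat_{network}"]
    df["pa"] = pa
    df = df.join(composites[["gmp", "gcp"]])
    return df.reset_index()


def fit_stage(profiles_df: pd.DataFrame, nat: pd.DataFrame,
              mean_nat: pd.DataFrame, composites: pd.DataFrame,
              pa: pd.Series, config: RunConfig, include_sequence=True):
    """Per-network beta GLMMs, moderation models and JN regions."""
    t0 = time.perf_counter()
    glmm_fits, mod_fits, jn_regions = {}, {}, {}
    spec = GLMMSpec(include_sequence=include_sequence)
    seq_controls = ("sequence",) if include_sequence else ()
    for net in config.networks:
        frame = glmm_frame(nat, profiles_df, net)
        glmm_fits[net] = fit_beta_glmm(frame, spec)
        mframe = moderation_frame(profiles_df, mean_nat, composites, pa, net)
        mod_fits[("gmp", net)] = fit_moderation(
            mframe, outcome="gmp", predictor="nat", moderator="pa",
            controls=("education", "dat", "age", "sex") + seq_controls)
        mod_fits[("gcp", net)] = fit_moderation(
            mframe, outcome="gcp", predictor="nat", moderator="education",
            controls=("pa", "dat", "age", "sex") + seq_controls)
        jn_regions[("gmp", net)] = johnson_neyman(mod_fits[("gmp", net)],
                                                  alpha=config.alpha)
        jn_regions[("gcp", net)] = johnson_neyman(mod_fits[("gcp", net)],
                                                  alpha=config.alpha)
    log.info("fit: %d GLMMs, %d moderation models [%.1fs]",
             len(glmm_fits), len(mod_fits), time.perf_counter() - t0)
    return glmm_fits, mod_fits, jn_regions


def _glmm_long_table(glmm_fits: dict) -> pd.DataFrame:
    rows = []
    for net, fit in glmm_fits.items():
        t = fit.table.reset_index(names="term")
        t.insert(0, "network", net)
        t["pseudo_r2"] = fit.pseudo_r2
        t["n_obs"] = fit.n_obs
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def _moderation_long_table(mod_fits: dict) -> pd.DataFrame:
    rows = []
    for (outcome, net), fit in mod_fits.items():
        t = fit.table.reset_index(names="term")
        t.insert(0, "network", net)
        t.insert(0, "outcome", outcome)
        t["f_pvalue"] = fit.f_pvalue
        t["n_obs"] = fit.n_obs
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def _jn_long_table(jn_regions: dict) -> pd.DataFrame:
    rows = []
    for (outcome, net), region in jn_regions.items():
        if region.regions:
            for lo, hi, direction in region.regions:
                rows.append((outcome, net, region.status, lo, hi, direction))
        else:
            rows.append((outcome, net, region.status, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["outcome", "network", "status",
                                       "lower", "upper", "direction"])


def _write_tsv(df: pd.DataFrame, path: Path, index=False):
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Precomputed-input loading
# ---------------------------------------------------------------------------

def load_matrices(matrices_dir, atlas: ROIAtlas) -> dict:
    """Read dense symmetric matrices, one ``<participant>.tsv`` per file."""
    matrices = {}
    for path in sorted(Path(matrices_dir).glob("*.tsv")):
        values = np.loadtxt(path, delimiter="\t")
        matrices[path.stem] = ConnectivityMatrix(
            values=values, roi_ids=atlas.roi_ids
        )
    if not matrices:
        raise ContractError(f"no matrix files (*.tsv) found in {matrices_dir}")
    return matrices


def load_batteries(batteries_path, directions_path) -> list:
    """Read a wide battery table plus its (test, direction, kind) companion."""
    wide = pd.read_csv(batteries_path, sep="\t")
    meta = pd.read_csv(directions_path, sep="\t").set_index("test")
    directions = meta["direction"].to_dict()
    kinds = meta["kind"].to_dict()
    out = []
    for row in wide.itertuples(index=False):
        d = row._asdict()
        pid = d.pop("participant")
        out.append(TestBatteryResult(participant=pid, scores=d,
                                     directions=directions, kinds=kinds))
    return out


# ---------------------------------------------------------------------------
# Top-level runs
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, write: bool = True) -> ResultsBundle:
    """Execute every stage and (optionally) write the results bundle.

    Re-running with the same config and seed reproduces the NAT table
    byte-identically and the model tables to numerical tolerance.
    """
    import warnings as _warnings

    collected = []
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        if config.synthetic:
            atlas, profiles, series, diaries = simulate_stage(config)
            matrices, tsnr = connect_stage(series, atlas)
            batteries = None
        else:
            atlas = (read_atlas(config.atlas_path) if config.atlas_path
                     else synthetic_atlas())
            profiles = pd.read_csv(config.covariates_path, sep="\t")
            matrices = load_matrices(config.matrices_dir, atlas)
            diaries = pd.read_csv(config.diaries_path, sep="\t")
            batteries = load_batteries(config.batteries_path,
                                       config.directions_path)
            tsnr = None
        profiles_df = (profiles if isinstance(profiles, pd.DataFrame)
                       else profiles_frame(profiles))
        # NAT is analysed in the patient group only; HC scans contribute the
        # tSNR check and the behavioral reference sample
        pd_ids = profiles_df.loc[profiles_df["group"] == "PD", "participant"]
        pd_matrices = {pid: matrices.get(pid) for pid in pd_ids}
        nat = attack_stage(pd_matrices, atlas, config)
        mean_nat, pa, batteries, composites = score_stage(
            profiles if not isinstance(profiles, pd.DataFrame) else profiles_df,
            nat, diaries, config, batteries=batteries)
        analysis_profiles = profiles_df.copy()
        analysis_profiles["pa"] = analysis_profiles["participant"].map(pa)
        glmm_fits, mod_fits, jn_regions = fit_stage(
            analysis_profiles, nat, mean_nat, composites, pa, config)
        collected = [str(w.message) for w in caught]

    bundle = ResultsBundle(
        config=config,
        profiles=profiles_df,
        nat=nat,
        mean_nat=mean_nat,
        composites=composites,
        pa=pa,
        tsnr=tsnr,
        glmm=glmm_fits,
        glmm_table=_glmm_long_table(glmm_fits),
        moderation=mod_fits,
        moderation_table=_moderation_long_table(mod_fits),
        jn=jn_regions,
        jn_table=_jn_long_table(jn_regions),
        provenance=_provenance(config),
        warnings=collected,
    )
    if write:
        write_bundle(bundle)
    return bundle


def write_bundle(bundle: ResultsBundle) -> Path:
    out = Path(bundle.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(bundle.profiles, out / "cohort.tsv")
    _write_tsv(bundle.nat, out / "nat_table.tsv")
    _write_tsv(bundle.mean_nat.reset_index(), out / "mean_nat.tsv")
    _write_tsv(bundle.composites.reset_index(), out / "composites.tsv")
    _write_tsv(bundle.pa.rename_axis("participant").reset_index(),
               out / "lifetime_pa.tsv")
    if bundle.tsnr is not None:
        _write_tsv(bundle.tsnr, out / "tsnr.tsv")
    _write_tsv(bundle.glmm_table, out / "glmm_coefficients.tsv")
    _write_tsv(bundle.moderation_table, out / "moderation_coefficients.tsv")
    _write_tsv(bundle.jn_table, out / "jn_regions.tsv")
    prov = dict(bundle.provenance)
    prov["warnings"] = bundle.warnings
    prov["complete"] = bundle.complete
    (out / "provenance.json").write_text(json.dumps(prov, indent=2,
                                                    default=str))
    return out


def sensitivity_subgroup(bundle: ResultsBundle, sequence: int = 2,
                         write: bool = False) -> ResultsBundle:
    """Refit all statistics on the PD subgroup scanned with one sequence.

    The sequence contrasts are dropped from every design (the subgroup has
    a single level). NAT records are restricted, not recomputed: the graphs
    themselves do not depend on covariates.
    """
    profiles = bundle.profiles
    keep = profiles[(profiles["group"] != "PD")
                    | (profiles["sequence"] == sequence)]
    n_pd = int((keep["group"] == "PD").sum())
    if n_pd == 0:
        raise ContractError(f"no PD participants with sequence {sequence}")
    ids = set(keep["participant"])
    nat = bundle.nat[bundle.nat["participant"].isin(ids)].reset_index(drop=True)
    mean_nat = bundle.mean_nat[bundle.mean_nat.index.isin(ids)]
    composites = bundle.composites[bundle.composites.index.isin(ids)]
    pa = bundle.pa[bundle.pa.index.isin(ids)]
    glmm_fits, mod_fits, jn_regions = fit_stage(
        keep, nat, mean_nat, composites, pa, bundle.config,
        include_sequence=False)
    sub = ResultsBundle(
        config=bundle.config,
        profiles=keep.reset_index(drop=True),
        nat=nat, mean_nat=mean_nat, composites=composites, pa=pa,
        tsnr=bundle.tsnr,
        glmm=glmm_fits, glmm_table=_glmm_long_table(glmm_fits),
        moderation=mod_fits,
        moderation_table=_moderation_long_table(mod_fits),
        jn=jn_regions, jn_table=_jn_long_table(jn_regions),
        provenance={**bundle.provenance, "subgroup_sequence": sequence},
    )
    if write:
        out = Path(bundle.config.out_dir) / f"sensitivity_seq{sequence}"
        sub.config = RunConfig(**{**asdict(bundle.config),
                                  "out_dir": str(out),
                                  "cohort": bundle.config.cohort})
        write_bundle(sub)
    return sub
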