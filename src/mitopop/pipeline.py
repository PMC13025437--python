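"""End-to-end analysis orchestration with seeded reproducibility.

Builds the three report tables of a single-locus phylogeography study from
an alignment + population map (or a count-only haplotype table):

* summary  — per-haplogroup diversity (n, S, Nhap, Hd, pi, k, Fu & Li's D)
* demography — neutrality tests with simulation p-values plus the
  sudden-expansion fit (SSD, rg, tau/theta0/theta1 with bootstrap CIs)
* divergence — pairwise isolation-with-migration estimates
  (theta, Ne_female, T, TMRCA, T_pop)

Every report carries a provenance header (package version, config hash,
master seed) and regenerating with the same config and seed is
byte-identical.  Stage sub-seeds are derived from the master seed with a
fixed spawn-key scheme so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
import time
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from . import __version__
from .divergence import (
    IMConfig,
    convert_divergence,
    im_mcmc,
    write_im_config,
    write_posterior_histograms,
)
from .iohap import (
    COMPLETE_DELETION,
    PopulationMap,
    parse_haplotype_table,
    read_alignment,
    subset_by_group,
)
from .mismatch import expansion_time, fit_expansion, spectrum_table
from .neutrality import (
    ON_S,
    attach_pvalue,
    fu_li_d,
    fus_fs,
    r2,
    significance_stars,
    tajimas_d,
)
from .sumstats import diversity_summary, pairwise_spectrum

log = logging.getLogger("mitopop")

__all__ = ["RunConfig", "run_summary", "run_demography", "run_divergence", "run_all"]

_STAGE_KEYS = {"summary": 1, "neutrality": 2, "mismatch": 3, "divergence": 4,
               "simulate": 5}


def stage_seed(master: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """Deterministic per-stage sub-seed derived from the master seed."""
    return np.random.SeedSequence(master, spawn_key=(_STAGE_KEYS[stage], index))


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; parse from a plain key=value file with
    :meth:`from_file`."""

    alignment: str | None = None
    popmap: str | None = None
    table: str | None = None
    outdir: str = "."
    site_policy: str = COMPLETE_DELETION
    n_sims: int = 10_000
    n_boot: int = 10_000
    rate_per_site_per_year: float = 1.1e-8
    generation_years: float = 1.5
    pairwise_rate: bool = False
    seed: int = 0
    # isolation-with-migration settings
    im_M_max: float = 10.0
    im_T_max: float = 5.0
    im_chain_length: int = 5_000_000
    im_burn_in: int = 1_000_000
    im_thinning: int = 50
    im_n_chains: int = 3
    min_group_size: int = 2

    def __post_init__(self):
        if self.rate_per_site_per_year <= 0 or self.generation_years <= 0:
            raise ValueError("rate and generation time must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
        types = {f.name: f.type for f in fields(cls)}
        args = {}
        for k, v in kv.items():
            if k not in types:
                raise ValueError(f"unknown config key {k!r}")
            t = types[k]
            if "int" in t:
                args[k] = int(v)
            elif "float" in t:
                args[k] = float(v)
            elif "bool" in t:
                args[k] = v.lower() in ("1", "true", "yes")
            else:
                args[k] = v
        return cls(**args)

    def digest(self) -> str:
        """Hash of all analysis-relevant settings (the output location is
        excluded: it cannot influence results)."""
        text = ";".join(
            f"{f.name}={getattr(self, f.name)}" for f in fields(self)
            if f.name != "outdir"
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def im_config(self, seed_seq: np.random.SeedSequence) -> IMConfig:
        return IMConfig(
            M_max=self.im_M_max, T_max=self.im_T_max,
            chain_length=self.im_chain_length, burn_in=self.im_burn_in,
            thinning=self.im_thinning, n_chains=self.im_n_chains,
            seed=int(seed_seq.generate_state(1)[0] % (2**31)),
        )


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"# mitopop {__version__}",
        f"# config_hash={config.digest()}",
        f"# seed={config.seed}",
    ]


def _load_inputs(config: RunConfig):
    aln = pmap = table = None
    if config.alignment:
        aln = read_alignment(config.alignment)
        if not config.popmap:
            raise ValueError("an alignment requires a population map")
        pmap = PopulationMap.read(config.popmap)
        missing = set(aln.ids) - set(pmap.assignments)
        if missing:
            raise ValueError(f"sequences missing from population map: {sorted(missing)[:5]}")
    if config.table:
        table = parse_haplotype_table(config.table, strict=False)
        for loc, declared, total in table.inconsistencies:
            log.warning(
                "locality %s: declared n=%d but haplotype counts sum to %d; "
                "using the declared n", loc, declared, total,
            )
    if aln is None and table is None:
        raise ValueError("need an alignment+popmap or a haplotype table")
    return aln, pmap, table


def _groups(aln, pmap, table):
    if pmap is not None:
        return list(pmap.haplogroups)
    return list(table.haplogroups)


def _fmt(x, nd=3):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{nd}f}"


def _write(path: Path, header_lines: list[str], colnames: list[str],
           rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        fh.write("\t".join(colnames) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def run_summary(config: RunConfig) -> Path:
    """Per-haplogroup diversity report (one row per group plus ALL)."""
    t0 = time.perf_counter()
    aln, pmap, table = _load_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    groups = _groups(aln, pmap, table)
    for grp in groups + ["ALL"]:
        if aln is not None:
            sub = aln if grp == "ALL" else subset_by_group(aln, pmap, grp)
            if sub.n < config.min_group_size:
                rows.append([grp, str(sub.n)] + ["NA"] * 7 + ["too few sequences"])
                continue
            ds = diversity_summary(sub, config.site_policy)
            fld = fu_li_d(sub, site_policy=config.site_policy)
            rows.append([
                grp, str(ds.n), str(ds.S), str(ds.Nhap),
                _fmt(ds.Hd), _fmt(ds.pi), _fmt(ds.pi_sd),
                _fmt(ds.k, 1), _fmt(fld.value if fld.defined else None), "",
            ])
        else:
            sub = table if grp == "ALL" else subset_by_group(table, None, grp)
            n = sub.grand_total
            nhap = len(sub.haplotype_counts())
            rows.append([grp, str(n), "NA", str(nhap), "NA", "NA", "NA",
                         "NA", "NA", "sequence-based statistics unavailable"])
    out = outdir / "summary.tsv"
    _write(out, _provenance(config),
           ["Haplogroup", "n", "S", "Nhap", "Hd", "pi", "pi_SD", "k",
            "FuLiDstar", "note"], rows)
    log.info("summary: %d groups, %.2fs", len(groups), time.perf_counter() - t0)
    return out


def run_demography(config: RunConfig) -> Path:
    """Neutrality + sudden-expansion report per haplogroup (and ALL)."""
    t0 = time.perf_counter()
    aln, pmap, _ = _load_inputs(config)
    if aln is None:
        raise ValueError("the demography stage requires sequence data")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    groups = _groups(aln, pmap, None)
    for gi, grp in enumerate(groups + ["ALL"]):
        sub = aln if grp == "ALL" else subset_by_group(aln, pmap, grp)
        if sub.n < 4:
            rows.append([grp, str(sub.n)] + ["NA"] * 14 + ["too few sequences"])
            continue
        seed_nt = stage_seed(config.seed, "neutrality", gi)
        rngs = [np.random.default_rng(s) for s in seed_nt.spawn(3)]
        d = attach_pvalue(tajimas_d, sub, n_sims=config.n_sims, seed=rngs[0],
                          site_policy=config.site_policy)
        fs = attach_pvalue(fus_fs, sub, n_sims=config.n_sims, seed=rngs[1],
                           site_policy=config.site_policy)
        r2s = attach_pvalue(r2, sub, n_sims=config.n_sims, seed=rngs[2],
                            site_policy=config.site_policy)
        seed_mm = int(stage_seed(config.seed, "mismatch", gi).generate_state(1)[0] % 2**31)
        spec = pairwise_spectrum(sub, config.site_policy)
        fit = fit_expansion(spec, n_boot=config.n_boot, seed=seed_mm)
        with open(outdir / f"mismatch_spectrum_{grp}.tsv", "w",
                  encoding="utf-8") as fh:
            fh.write("differences\tobserved\texpected\n")
            for i, o, e in spectrum_table(spec, fit):
                fh.write(f"{i}\t{o:.6g}\t{e:.6g}\n")
        et = expansion_time(
            fit.tau, sub.length, config.rate_per_site_per_year,
            config.generation_years, ci_tau=fit.ci_tau,
            pairwise_rate=config.pairwise_rate,
        )
        fmt_ci = lambda ci: "NA" if ci is None else f"({ci[0]:.2f}~{ci[1]:.2f})"
        rows.append([
            grp, str(sub.n),
            _fmt(d.value if d.defined else None) + significance_stars(d.p_value),
            _fmt(d.p_value),
            (_fmt(fs.value if fs.defined else None)
             + significance_stars(fs.p_value)),
            _fmt(fs.p_value),
            _fmt(r2s.value if r2s.defined else None) + significance_stars(r2s.p_value),
            _fmt(r2s.p_value),
            _fmt(fit.SSD), _fmt(fit.p_SSD), _fmt(fit.rg), _fmt(fit.p_rg),
            f"{fit.tau:.2f} {fmt_ci(fit.ci_tau)}",
            f"{fit.theta0:.2f} {fmt_ci(fit.ci_theta0)}",
            f"{fit.theta1:.2f} {fmt_ci(fit.ci_theta1)}",
            _fmt(et.t_years, 0),
            "" if fit.converged else "expansion fit did not converge",
        ])
    out = outdir / "demography.tsv"
    hdr = _provenance(config) + [
        f"# n_sims={config.n_sims} n_boot={config.n_boot} conditioning={ON_S}",
        "# one-tailed (lower) p-values; stars: * p<0.05, ** p<0.01, *** p<0.001",
    ]
    _write(out, hdr,
           ["Haplogroup", "n", "TajimaD", "p_D", "FuFs", "p_Fs", "R2", "p_R2",
            "SSD", "p_SSD", "rg", "p_rg", "tau_95CI", "theta0_95CI",
            "theta1_95CI", "expansion_time_years", "note"], rows)
    log.info("demography: %.2fs", time.perf_counter() - t0)
    return out


def run_divergence(config: RunConfig) -> Path:
    """Pairwise isolation-with-migration report across haplogroups."""
    t0 = time.perf_counter()
    aln, pmap, _ = _load_inputs(config)
    if aln is None:
        raise ValueError("the divergence stage requires sequence data")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = _groups(aln, pmap, None)
    rows = []
    for pi_, (g1, g2) in enumerate(itertools.combinations(groups, 2)):
        a1 = subset_by_group(aln, pmap, g1)
        a2 = subset_by_group(aln, pmap, g2)
        if a1.n < config.min_group_size or a2.n < config.min_group_size:
            log.warning("skipping pair %s-%s: too few sequences", g1, g2)
            continue
        cfg = config.im_config(stage_seed(config.seed, "divergence", pi_))
        est = im_mcmc(a1, a2, cfg)
        write_posterior_histograms(
            est, outdir / f"divergence_posterior_{g1}_{g2}.tsv")
        write_im_config(cfg, outdir / f"im_config_{g1}_{g2}.txt")
        conv = convert_divergence(
            est.theta_mode, est.T_mode, est.TMRCA_mode, aln.length,
            config.rate_per_site_per_year, config.generation_years,
            pairwise_rate=config.pairwise_rate,
        )
        rows.append([
            g1, g2, _fmt(est.theta_mode, 2), _fmt(conv["Ne_female"], 0),
            _fmt(est.T_mode, 2), _fmt(est.TMRCA_mode, 2),
            _fmt(conv["TMRCA_Myr"], 3), _fmt(conv["T_pop_Myr"], 3),
            ";".join(est.warnings),
        ])
    out = outdir / "divergence.tsv"
    hdr = _provenance(config) + [
        f"# M_max={config.im_M_max} T_max={config.im_T_max} "
        f"chain={config.im_chain_length} burn_in={config.im_burn_in} "
        f"chains={config.im_n_chains}",
    ]
    _write(out, hdr,
           ["Haplogroup1", "Haplogroup2", "theta", "Ne_female", "T",
            "T_MRCA", "T_MRCA_Myr", "T_pop_Myr", "warnings"], rows)
    log.info("divergence: %d pairs, %.2fs", len(rows), time.perf_counter() - t0)
    return out


def run_all(config: RunConfig) -> list[Path]:
    return [run_summary(config), run_demography(config), run_divergence(config)]
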