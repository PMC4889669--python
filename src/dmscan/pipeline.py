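"""End-to-end orchestration: simulate/load -> scan -> thresholds -> report.

A run is driven by a single configuration (YAML/JSON-compatible dict) naming
either input files (marker map + genotype table) or a simulation block, the
strata to analyze, and which scans to perform.  Outputs are TSV tables (one
per scan), a machine-readable JSON summary with provenance (config hash,
seed, package version), and structured log records with per-stage timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .io import (
    read_genotype_table,
    read_marker_panel,
    write_genotype_table,
    write_marker_panel,
)
from .markers import (
    CrossDesign,
    CrossKind,
    GenotypeTable,
    MarkerPanel,
    default_panel,
)
from .epistasis import (
    bonferroni_alpha,
    chi2_upper_quantile,
    enumerate_tests,
    interaction_scan,
)
from .segdist import single_locus_scan
from .simulate import (
    RecombinationModel,
    SexModel,
    SimConfig,
    ViabilityModel,
    simulate_cross,
)

log = logging.getLogger("dmscan")

VALID_SCANS = ("single", "pairs", "triples")
GROUPABLE = (
    "cross_id", "sex", "stage", "temperature_C", "maternal_population",
)


@dataclass
class RunConfig:
    """Validated run configuration."""

    markers_path: Optional[str] = None
    genotypes_path: Optional[str] = None
    simulate: Optional[dict] = None
    strata: Dict[str, dict] = field(default_factory=lambda: {"all": {}})
    scans: List[str] = field(default_factory=lambda: ["single", "pairs"])
    family_alpha: float = 0.05
    df_policy: str = "paper_12"
    n_perm: int = 0
    seed: Optional[int] = None
    out_dir: str = "dmscan_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("configuration must be a mapping")
        known = {
            "markers", "genotypes", "simulate", "strata", "scans",
            "family_alpha", "df_policy", "n_perm", "seed", "out",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        has_paths = "genotypes" in raw
        has_sim = "simulate" in raw
        if has_paths == has_sim:
            raise ConfigError(
                "exactly one of 'genotypes' (with 'markers') or 'simulate' "
                "must be given"
            )
        if has_paths and "markers" not in raw:
            raise ConfigError("'genotypes' requires a 'markers' path")
        cfg = cls(
            markers_path=raw.get("markers"),
            genotypes_path=raw.get("genotypes"),
            simulate=raw.get("simulate"),
            strata=raw.get("strata", {"all": {}}),
            scans=list(raw.get("scans", ["single", "pairs"])),
            family_alpha=float(raw.get("family_alpha", 0.05)),
            df_policy=str(raw.get("df_policy", "paper_12")),
            n_perm=int(raw.get("n_perm", 0)),
            seed=raw.get("seed"),
            out_dir=str(raw.get("out", "dmscan_out")),
        )
        for s in cfg.scans:
            if s not in VALID_SCANS:
                raise ConfigError(f"unknown scan {s!r}; valid: {VALID_SCANS}")
        if not (0.0 < cfg.family_alpha < 1.0):
            raise ConfigError(f"family_alpha must be in (0,1), got {cfg.family_alpha}")
        if cfg.df_policy not in ("paper_12", "loglinear_8"):
            raise ConfigError(f"unknown df_policy {cfg.df_policy!r}")
        if not isinstance(cfg.strata, dict) or not cfg.strata:
            raise ConfigError("strata must be a non-empty mapping")
        stochastic = has_sim or cfg.n_perm > 0
        if stochastic and cfg.seed is None:
            raise ConfigError("a seed is required when simulation or "
                              "permutation is enabled")
        return cfg

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                raw = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
        return cls.from_dict(raw or {})

    def canonical_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _viability_from_dict(raw: Optional[dict]) -> ViabilityModel:
    if not raw:
        return ViabilityModel()
    single = {m: tuple(w) for m, w in (raw.get("single_locus") or {}).items()}
    epistatic = [
        (tuple(e["markers"]), np.asarray(e["table"], dtype=float))
        for e in (raw.get("epistatic") or [])
    ]
    return ViabilityModel(single_locus=single, epistatic=epistatic)


def _sim_table(config: RunConfig) -> GenotypeTable:
    raw = dict(config.simulate or {})
    panel = (
        read_marker_panel(raw["markers"]) if "markers" in raw else default_panel()
    )
    kind = CrossKind(raw.get("design", "F2_INTERCROSS"))
    design = CrossDesign(
        kind=kind,
        f1_parent_sex=raw.get("f1_parent_sex", "NA"),
        recurrent_population=raw.get("recurrent_population", "NA"),
    )
    sex_raw = raw.get("sex_model") or {}
    sex_model = SexModel(
        kind=sex_raw.get("kind", "bernoulli_half"),
        effects=tuple(
            (e["marker"], float(e["effect"])) for e in sex_raw.get("effects", [])
        ),
    )
    sim = SimConfig(
        panel=panel,
        design=design,
        n_offspring=int(raw.get("n_offspring", 200)),
        seed=int(config.seed),
        recombination=RecombinationModel(
            female_recombination=float(raw.get("female_recombination", 0.0))
        ),
        viability=_viability_from_dict(raw.get("viability")),
        sex_model=sex_model,
        maternal_population=raw.get("maternal_population", "P2"),
        cross_id=raw.get("cross_id", "sim"),
        temperature_C=raw.get("temperature_C"),
    )
    return simulate_cross(sim)


@dataclass
class RunSummary:
    """Machine-readable account of one pipeline run."""

    scans: Dict[str, dict]
    strata_sizes: Dict[str, int]
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "scans": self.scans,
                "strata_sizes": self.strata_sizes,
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
        )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.8g")


def run(config: RunConfig) -> RunSummary:
    """Execute all configured stages; writes outputs under config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if config.simulate is not None:
        table = _sim_table(config)
        write_marker_panel(table.panel, out / "markers.tsv")
        write_genotype_table(table, out / "genotypes.tsv")
        log.info("simulate: %d offspring in %.2fs", table.n_individuals,
                 time.perf_counter() - t0)
    else:
        panel = read_marker_panel(config.markers_path)
        table = read_genotype_table(config.genotypes_path, panel)
        log.info("load: %d individuals x %d markers", table.n_individuals,
                 len(panel))

    strata = {name: (spec or None) for name, spec in config.strata.items()}
    from .markers import resolve_stratum

    strata_sizes = {
        name: int(resolve_stratum(table, spec).sum())
        for name, spec in strata.items()
    }

    scans_summary: Dict[str, dict] = {}
    if "single" in config.scans:
        t = time.perf_counter()
        df = single_locus_scan(table, strata, family_alpha=config.family_alpha)
        _write_tsv(df, out / "single_locus.tsv")
        scans_summary["single"] = {
            "n_markers": table.panel.n_markers,
            "n_tests": table.panel.n_markers,
            "alpha_bonf": bonferroni_alpha(
                config.family_alpha, table.panel.n_markers
            ),
            "n_significant_bonf": int(df["significant"].fillna(0).sum()),
            "n_rows": len(df),
        }
        log.info("scan single: %d rows in %.2fs", len(df), time.perf_counter() - t)

    for scan_name, order in (("pairs", 2), ("triples", 3)):
        if scan_name not in config.scans:
            continue
        t = time.perf_counter()
        enum = enumerate_tests(table.panel, order)
        df = interaction_scan(
            table, order, strata,
            df_policy=config.df_policy,
            family_alpha=config.family_alpha,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        _write_tsv(df, out / f"{scan_name}.tsv")
        n_sparse = int((pd.to_numeric(df["n_complete"], errors="coerce") < 30).sum())
        if n_sparse:
            log.warning("scan %s: %d tuples with < 30 complete cases",
                        scan_name, n_sparse)
        scans_summary[scan_name] = {
            "n_markers": table.panel.n_markers,
            "n_tests": enum.n_tests,
            "alpha_bonf": (
                bonferroni_alpha(config.family_alpha, enum.n_tests)
                if enum.n_tests else None
            ),
            "n_significant_bonf": int(df["significant_bonf"].fillna(0).sum()),
            "n_significant_p001": int(df["significant_p001"].fillna(0).sum()),
            "n_rows": len(df),
        }
        log.info("scan %s: %d rows in %.2fs", scan_name, len(df),
                 time.perf_counter() - t)

    summary = RunSummary(
        scans=scans_summary,
        strata_sizes=strata_sizes,
        provenance={
            "config_hash": config.canonical_hash(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    (out / "summary.json").write_text(summary.to_json(), encoding="utf-8")
    log.info("run complete in %.2fs", time.perf_counter() - t0)
    return summary


def thresholds_table(
    panel: MarkerPanel, family_alpha: float = 0.05
) -> pd.DataFrame:
    """Bonferroni thresholds and critical chi-squares for a panel."""
    rows = []
    rows.append(
        {
            "family": "single_locus",
            "n_tests": panel.n_markers,
            "alpha_bonf": bonferroni_alpha(family_alpha, panel.n_markers),
            "df": 2,
            "critical_chi2": chi2_upper_quantile(
                bonferroni_alpha(family_alpha, panel.n_markers), 2
            ),
        }
    )
    for name, order, df in (("pairs", 2, 4), ("triples", 3, 12)):
        enum = enumerate_tests(panel, order)
        if enum.n_tests == 0:
            continue
        alpha = bonferroni_alpha(family_alpha, enum.n_tests)
        rows.append(
            {
                "family": name,
                "n_tests": enum.n_tests,
                "alpha_bonf": alpha,
                "df": df,
                "critical_chi2": chi2_upper_quantile(alpha, df),
            }
        )
    return pd.DataFrame(rows)


def report(results_dir: Union[str, Path]) -> Dict[str, pd.DataFrame]:
    """Human-readable tables from a completed run directory.

    Produces a per-marker table (chromosome order, w +/- SE, significance
    flags) and interaction tables restricted to tuples below the relaxed
    p < 0.001 threshold with Bonferroni survivors marked.  Flags are taken
    verbatim from the scan TSVs — no re-thresholding.
    """
    results_dir = Path(results_dir)
    out: Dict[str, pd.DataFrame] = {}
    single_path = results_dir / "single_locus.tsv"
    if single_path.exists():
        df = pd.read_csv(single_path, sep="\t", na_values="NA",
                         keep_default_na=False, dtype={"chromosome": str})
        cols = [
            "marker_id", "chromosome", "stratum", "n0", "n1", "n2",
            "w_P1", "se_P1", "w_P2", "se_P2", "p", "significant", "error",
        ]
        out["markers"] = df[cols]
        out["markers"].to_csv(
            results_dir / "report_markers.tsv", sep="\t", index=False,
            na_rep="NA",
        )
    for scan in ("pairs", "triples"):
        path = results_dir / f"{scan}.tsv"
        if not path.exists():
            continue
        df = pd.read_csv(path, sep="\t", na_values="NA", keep_default_na=False)
        hits = df[pd.to_numeric(df["significant_p001"], errors="coerce") == 1]
        out[scan] = hits.reset_index(drop=True)
        out[scan].to_csv(
            results_dir / f"report_{scan}.tsv", sep="\t", index=False,
            na_rep="NA",
        )
    if not out:
        raise DataError(f"{results_dir}: no scan outputs found")
    return out
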