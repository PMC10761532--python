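"""Configuration, orchestration, and report generation.

A single YAML config drives every stage: species prediction, mass table,
CD-MS simulation/loading and quantification, gel simulation/loading and
band quantification, termination profiles, and the CD-MS-vs-gel
comparison.  All stochastic stages carry explicit seeds, so a run is fully
reproducible: identical config plus seeds gives byte-identical outputs.
Every CSV written by the pipeline starts with a comment line recording the
config hash and the stage seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cdms_quant, cdms_synth, gel_model, genome_model, mass_model
from . import termination_stats as term
from .errors import AavpackError, ConfigError
from .cdms_quant import SubpopulationQuant
from .cdms_synth import IonEvent, MixtureSpec, SimConfig
from .gel_model import BandQuant, LaneConfig
from .genome_model import ConstructDef, MultimerSpecies
from .mass_model import CapsidModel, MassModelParams, SpeciesMassTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CdmsSettings:
    seed: int
    mixture: dict[str, float]
    n_ions: int = 10_000
    mode: str = "standard"
    charge_mean: float = cdms_synth.DEFAULT_CHARGE_MEAN
    charge_spread: float = cdms_synth.DEFAULT_CHARGE_SPREAD
    mz_cv: float = cdms_synth.DEFAULT_MZ_CV
    bin_width: float = cdms_quant.DEFAULT_BIN_WIDTH
    ions_path: str | None = None

    def sim_config(self) -> SimConfig:
        return SimConfig.preset(
            self.mode,
            seed=self.seed,
            n_ions=self.n_ions,
            charge_mean=self.charge_mean,
            charge_spread=self.charge_spread,
            mz_cv=self.mz_cv,
        )


@dataclass(frozen=True)
class GelSettings:
    seed: int
    band_fractions: dict[str, float]
    mobility_a: float = gel_model.DEFAULT_MOBILITY_A
    mobility_b: float = gel_model.DEFAULT_MOBILITY_B
    band_sigma: float = gel_model.DEFAULT_BAND_SIGMA
    noise_sigma: float = gel_model.DEFAULT_NOISE_SIGMA
    window_half_width: float = gel_model.DEFAULT_WINDOW_HALF_WIDTH
    molar_correction: bool = False
    lane_path: str | None = None

    def lane_config(self) -> LaneConfig:
        return LaneConfig(
            mobility_a=self.mobility_a,
            mobility_b=self.mobility_b,
            band_sigma=self.band_sigma,
            noise_sigma=self.noise_sigma,
        )


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-resolved configuration for one pipeline run."""

    construct: ConstructDef
    capsid: CapsidModel
    mass_params: MassModelParams
    window_half_width: float
    cdms: CdmsSettings | None
    gel: GelSettings | None
    output_dir: str = "out"
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing required config key {key!r} in {context}")
    return mapping[key]


def config_from_dict(raw: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed YAML mapping."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    c = _require(raw, "construct", "config")
    construct = ConstructDef(
        name=str(_require(c, "name", "construct")),
        unit_length=int(_require(c, "unit_length", "construct")),
        itr_junction_length=int(
            c.get("itr_junction_length", genome_model.DEFAULT_ITR_JUNCTION_LENGTH)
        ),
        capacity=int(c.get("capacity", genome_model.DEFAULT_CAPACITY)),
    )
    cap = _require(raw, "capsid", "config")
    capsid = CapsidModel(
        vp1_mass=float(_require(cap, "vp1_mass", "capsid")),
        vp2_mass=float(_require(cap, "vp2_mass", "capsid")),
        vp3_mass=float(_require(cap, "vp3_mass", "capsid")),
        vp1_count=int(cap.get("vp1_count", 5)),
        vp2_count=int(cap.get("vp2_count", 5)),
        vp3_count=int(cap.get("vp3_count", 50)),
    )
    mp = raw.get("mass_params", {})
    mass_params = MassModelParams(
        avg_nt_mass=float(mp.get("avg_nt_mass", mass_model.DEFAULT_AVG_NT_MASS)),
        counterion_factor=float(
            mp.get("counterion_factor", mass_model.DEFAULT_COUNTERION_FACTOR)
        ),
    )
    window_half_width = float(
        mp.get("window_half_width", mass_model.DEFAULT_WINDOW_HALF_WIDTH)
    )

    cdms = None
    if "cdms" in raw:
        cd = raw["cdms"]
        cdms = CdmsSettings(
            seed=int(_require(cd, "seed", "cdms")),
            mixture={str(k): float(v) for k, v in _require(cd, "mixture", "cdms").items()},
            n_ions=int(cd.get("n_ions", 10_000)),
            mode=str(cd.get("mode", "standard")),
            charge_mean=float(cd.get("charge_mean", cdms_synth.DEFAULT_CHARGE_MEAN)),
            charge_spread=float(
                cd.get("charge_spread", cdms_synth.DEFAULT_CHARGE_SPREAD)
            ),
            mz_cv=float(cd.get("mz_cv", cdms_synth.DEFAULT_MZ_CV)),
            bin_width=float(cd.get("bin_width", cdms_quant.DEFAULT_BIN_WIDTH)),
            ions_path=cd.get("ions_path"),
        )
    gel = None
    if "gel" in raw:
        g = raw["gel"]
        gel = GelSettings(
            seed=int(_require(g, "seed", "gel")),
            band_fractions={
                str(k): float(v)
                for k, v in _require(g, "band_fractions", "gel").items()
            },
            mobility_a=float(g.get("mobility_a", gel_model.DEFAULT_MOBILITY_A)),
            mobility_b=float(g.get("mobility_b", gel_model.DEFAULT_MOBILITY_B)),
            band_sigma=float(g.get("band_sigma", gel_model.DEFAULT_BAND_SIGMA)),
            noise_sigma=float(g.get("noise_sigma", gel_model.DEFAULT_NOISE_SIGMA)),
            window_half_width=float(
                g.get("window_half_width", gel_model.DEFAULT_WINDOW_HALF_WIDTH)
            ),
            molar_correction=bool(g.get("molar_correction", False)),
            lane_path=g.get("lane_path"),
        )
    return RunConfig(
        construct=construct,
        capsid=capsid,
        mass_params=mass_params,
        window_half_width=window_half_width,
        cdms=cdms,
        gel=gel,
        output_dir=str(raw.get("output_dir", "out")),
        raw=raw,
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def write_stage_csv(
    frame: pd.DataFrame, path, config: RunConfig, seed: int | None = None
) -> None:
    """Write a stage CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# aavpack config_hash={config.config_hash} seed={seed}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")


@dataclass
class RunReport:
    """Everything a pipeline run produced, plus output paths."""

    species: list[MultimerSpecies]
    mass_table: SpeciesMassTable
    ion_quant: SubpopulationQuant | None = None
    band_quant: BandQuant | None = None
    cdms_profile: term.TerminationProfile | None = None
    gel_profile: term.TerminationProfile | None = None
    comparison: term.ProfileComparison | None = None
    outputs: dict[str, str] = field(default_factory=dict)


def packaged_abundances(
    quant: SubpopulationQuant, species: list[MultimerSpecies]
) -> list[float]:
    """Packaged-species ion counts in ascending ITR order (empties and
    unassigned ions excluded)."""
    return [
        float(quant.ion_counts[s.label]) for s in species if not s.is_empty
    ]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, AavpackError):
                raise AavpackError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every configured stage and write all outputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_lines = [f"aavpack run — construct {config.construct.name}"]

    with _stage("predict-species"):
        species = genome_model.full_species_list(config.construct)
        if len(species) < 2:
            raise ConfigError(
                f"no packageable species for construct {config.construct.name}"
            )
        frame = genome_model.species_frame(species)
        write_stage_csv(frame, outdir / "species.csv", config)

    with _stage("mass-table"):
        table = mass_model.build_mass_table(
            species, config.capsid, config.mass_params, config.window_half_width
        )
        write_stage_csv(table.to_frame(), outdir / "mass_table.csv", config)

    report = RunReport(species=species, mass_table=table)
    report.outputs["species"] = str(outdir / "species.csv")
    report.outputs["mass_table"] = str(outdir / "mass_table.csv")

    if config.cdms is not None:
        cd = config.cdms
        with _stage("cdms"):
            if cd.ions_path:
                events = cdms_synth.read_ions(cd.ions_path)
            else:
                mixture = MixtureSpec.from_abundances(cd.mixture)
                events = cdms_synth.simulate_ions(mixture, table, cd.sim_config())
                cdms_synth.write_ions(events, outdir / "ions.csv")
                report.outputs["ions"] = str(outdir / "ions.csv")
            quant = cdms_quant.assign_ions(events, table)
            charges = cdms_quant.charge_summary(events, quant)
            spectrum = cdms_quant.build_spectrum(events, cd.bin_width)
            qframe = quant.to_frame().merge(
                charges.to_frame(), on="label", how="left"
            )
            write_stage_csv(qframe, outdir / "ion_quant.csv", config, cd.seed)
            write_stage_csv(
                spectrum.to_frame(), outdir / "spectrum.csv", config, cd.seed
            )
            report.ion_quant = quant
            report.outputs["ion_quant"] = str(outdir / "ion_quant.csv")
            report.outputs["spectrum"] = str(outdir / "spectrum.csv")

        with _stage("terminate-cdms"):
            counts = packaged_abundances(quant, species)
            profile = term.termination_profile(
                counts, source="cdms", construct=config.construct.name
            )
            write_stage_csv(
                profile.to_frame(), outdir / "termination_cdms.csv", config, cd.seed
            )
            report.cdms_profile = profile
            report.outputs["termination_cdms"] = str(outdir / "termination_cdms.csv")
            report_lines.append(
                term.profile_report(profile, total_count=int(sum(counts)))
            )
            report_lines.append(
                "  empty fraction: "
                + term.format_percent(quant.rel_abundance(genome_model.EMPTY_LABEL))
                + "; unassigned: "
                + term.format_percent(
                    quant.unassigned_count / quant.total_ions
                )
            )

    if config.gel is not None:
        g = config.gel
        with _stage("gel"):
            lane_cfg = g.lane_config()
            if g.lane_path:
                lane = gel_model.GelLane.from_frame(
                    pd.read_csv(g.lane_path, comment="#"), lane_cfg
                )
            else:
                fractions_total = sum(g.band_fractions.values())
                fractions = {
                    k: v / fractions_total for k, v in g.band_fractions.items()
                }
                lane = gel_model.simulate_lane(fractions, species, lane_cfg, g.seed)
                write_stage_csv(lane.to_frame(), outdir / "lane.csv", config, g.seed)
                report.outputs["lane"] = str(outdir / "lane.csv")
            bands = gel_model.quantify_bands(lane, species, g.window_half_width)
            molar = None
            if g.molar_correction:
                lengths = {s.label: s.nt_length for s in species if not s.is_empty}
                molar = gel_model.molar_correct(bands.intensity_fractions, lengths)
            write_stage_csv(
                bands.to_frame(molar), outdir / "band_quant.csv", config, g.seed
            )
            report.band_quant = bands
            report.outputs["band_quant"] = str(outdir / "band_quant.csv")

        with _stage("terminate-gel"):
            fracs = bands.intensity_fractions
            ordered = [
                fracs[s.label] for s in species if not s.is_empty
            ]
            profile = term.termination_profile(
                ordered, source="gel", construct=config.construct.name
            )
            write_stage_csv(
                profile.to_frame(), outdir / "termination_gel.csv", config, g.seed
            )
            report.gel_profile = profile
            report.outputs["termination_gel"] = str(outdir / "termination_gel.csv")
            report_lines.append(term.profile_report(profile))

    if report.cdms_profile is not None and report.gel_profile is not None:
        with _stage("compare"):
            comparison = term.compare_profiles(
                report.cdms_profile, report.gel_profile
            )
            write_stage_csv(
                comparison.to_frame(), outdir / "profile_comparison.csv", config
            )
            report.comparison = comparison
            report.outputs["profile_comparison"] = str(
                outdir / "profile_comparison.csv"
            )
            report_lines.append(
                f"CD-MS vs gel total variation distance: "
                f"{comparison.total_variation:.4f}"
            )

    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(report_lines) + "\n")
    report.outputs["report"] = str(report_path)
    return report
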