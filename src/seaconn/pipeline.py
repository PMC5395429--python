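"""Pipeline orchestration, GENEPOP I/O and run manifests.

Ties the stages together behind one YAML-configured entry point
(synthetic field -> dispersal -> connectivity; synthetic genotypes ->
population genetics; forward simulation), with per-stage seeds recorded
in a manifest so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectivity import FluxTable, effectiveness, interannual_trends, persistence, rate_decomposition
from .dispersal_sim import DispersalConfig, load_sites_csv, run_simulation, study_sites
from .field_model import GridSpec, load_field, write_field
from .forward_sim import ForwardModel, PowerResult, powsim_power, simulate_drift_fst
from .popgen import (GenotypeDataset, MISSING, amova, apply_standard_filters,
                     diversity_table, pairwise_fst, scan_partitions, wc_theta)
from .synthetic_data import (SyntheticFieldParams, SyntheticGenotypeParams,
                             make_synthetic_field, simulate_genotype_dataset)

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# GENEPOP I/O
# ----------------------------------------------------------------------

class GenepopFormatError(ValueError):
    """A GENEPOP file violates the 2-/3-digit dialect."""


def write_genepop(dataset: GenotypeDataset, path, digits: int = 2,
                  title: str = "seaconn export") -> None:
    """Write biallelic genotypes as GENEPOP (allele codes 01/02 or 001/002).

    SNPs of multi-SNP loci are emitted as separate GENEPOP loci named
    ``<locus>_<pos>`` so the locus structure round-trips.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    a1 = f"{1:0{digits}d}"
    a2 = f"{2:0{digits}d}"
    a0 = "0" * digits
    code = {0: a1 + a1, 1: a1 + a2, 2: a2 + a2, MISSING: a0 + a0}
    lines = [title]
    multi = np.bincount(dataset.snp_locus, minlength=dataset.n_loci).max() > 1
    for j in range(dataset.n_snps):
        name = dataset.locus_names[dataset.snp_locus[j]]
        lines.append(f"{name}_{dataset.snp_pos[j]}" if multi else name)
    current = None
    for i, pop in enumerate(dataset.pop_labels):
        if pop != current:
            lines.append("POP")
            current = pop
        geno = " ".join(code[int(g)] for g in dataset.genotypes[i])
        lines.append(f"{dataset.individual_names[i]} ,  {geno}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path) -> GenotypeDataset:
    """Parse a GENEPOP file (2- or 3-digit dialect) into a dataset.

    Locus names of the form ``<name>_<k>`` with k in 1..3 are folded back
    into multi-SNP loci.  The first allele code seen per locus is mapped to
    dosage 0; biallelic coding is enforced.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    if len(lines) < 3:
        raise GenepopFormatError("file too short for GENEPOP")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        # locus names: one per line, or comma-separated on one line
        locus_names.extend(n.strip() for n in lines[i].split(",") if n.strip())
        i += 1
    if not locus_names or i == len(lines):
        raise GenepopFormatError("no locus names or no POP delimiter found")

    inds, pops, genos = [], [], []
    pop_idx = 0
    digits = None
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        if line.strip().upper() == "POP":
            pop_idx += 1
            continue
        if "," not in line:
            raise GenepopFormatError(f"line {lineno}: missing ',' separator")
        name, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise GenepopFormatError(
                f"line {lineno}: {len(tokens)} genotypes for "
                f"{len(locus_names)} loci")
        if digits is None:
            width = len(tokens[0])
            if width not in (4, 6):
                raise GenepopFormatError(
                    f"line {lineno}: genotype width {width} is not a "
                    "2- or 3-digit diploid encoding")
            digits = width // 2
        row = []
        for tok in tokens:
            if len(tok) != 2 * digits or not tok.isdigit():
                raise GenepopFormatError(
                    f"line {lineno}: malformed genotype {tok!r}")
            row.append((int(tok[:digits]), int(tok[digits:])))
        inds.append(name.strip())
        pops.append(f"POP{pop_idx}")
        genos.append(row)
    if not genos:
        raise GenepopFormatError("no individuals found")

    n_snps = len(locus_names)
    genotypes = np.full((len(genos), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        alleles = sorted({al for row in genos for al in row[j] if al != 0})
        if len(alleles) > 2:
            raise GenepopFormatError(f"locus {locus_names[j]} has >2 alleles")
        # dosage counts the highest-numbered allele code (writer emits 01/02)
        counted = alleles[-1] if alleles and alleles[-1] != 1 else None
        for i_ind, row in enumerate(genos):
            a, b = row[j]
            if a == 0 or b == 0:
                continue
            genotypes[i_ind, j] = (a == counted) + (b == counted)

    # fold SNP_<pos> names back into loci
    base_pos = []
    for name in locus_names:
        if "_" in name and name.rsplit("_", 1)[1].isdigit():
            base, pos = name.rsplit("_", 1)
            base_pos.append((base, int(pos)))
        else:
            base_pos.append((name, 1))
    loci = list(dict.fromkeys(b for b, _ in base_pos))
    locus_index = {b: k for k, b in enumerate(loci)}
    snp_locus = np.array([locus_index[b] for b, _ in base_pos])
    snp_pos = np.array([p for _, p in base_pos])

    return GenotypeDataset(genotypes=genotypes, snp_locus=snp_locus,
                           snp_pos=snp_pos, locus_names=loci,
                           individual_names=inds, pop_labels=pops)


# ----------------------------------------------------------------------
# manifest and orchestration
# ----------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record of a pipeline run."""

    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config_path, out_dir=None) -> RunManifest:
    """Execute the stages requested in a YAML config; write a manifest.

    Recognized stages: synth_field, dispersal, connectivity,
    synth_genotypes, popgen, forward_sim.  Each stage draws its seed from
    the master seed, so rerunning an identical config reproduces
    byte-identical outputs.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict) or "stages" not in cfg:
        raise ValueError("config must be a mapping with a 'stages' list")
    out = Path(out_dir or cfg.get("out_dir", "seaconn_out"))
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg.get("seed", 0))
    manifest = RunManifest(config=cfg)
    manifest.input_digests[str(config_path)] = _sha256(config_path)

    field_obj = None
    flux = None
    dataset = None

    for stage in cfg["stages"]:
        t0 = time.perf_counter()
        seed = _stage_seed(master, stage)
        manifest.seeds[stage] = seed
        params = cfg.get(stage, {}) or {}
        logger.info("stage %s (seed %d)", stage, seed)

        if stage == "synth_field":
            gp = dict(params.get("grid", {
                "lon_min": 15.0, "lon_max": 20.0, "lat_min": 39.5,
                "lat_max": 44.0, "d_lon": 0.1, "d_lat": 0.1,
                "depth_levels": (1.0, 5.0, 10.0),
                "time_origin": "2004-01-01", "n_days": 365,
            }))
            if isinstance(gp.get("time_origin"), str):
                gp["time_origin"] = datetime.date.fromisoformat(gp["time_origin"])
            if "depth_levels" in gp:
                gp["depth_levels"] = tuple(gp["depth_levels"])
            grid = GridSpec(**gp)
            fp = {k: v for k, v in params.items() if k != "grid"}
            if "gyre_centers" in fp:
                fp["gyre_centers"] = tuple(tuple(c) for c in fp["gyre_centers"])
            field_obj = make_synthetic_field(
                SyntheticFieldParams(domain=grid, seed=seed, **fp))
            path = out / "field.nc"
            write_field(field_obj, path)
            manifest.outputs["field"] = str(path)

        elif stage == "dispersal":
            if field_obj is None:
                if "field" not in params:
                    raise ValueError("dispersal stage needs a field "
                                     "(run synth_field or give 'field')")
                field_obj = load_field(params["field"])
            sites = (load_sites_csv(params["sites"]) if "sites" in params
                     else study_sites())
            dc = {k: v for k, v in params.items() if k not in ("field", "sites")}
            for key in ("years", "spawn_start", "spawn_end", "pld_bounds"):
                if key in dc:
                    dc[key] = tuple(dc[key])
            config = DispersalConfig(seed=seed, **dc)
            flux = run_simulation(field_obj, sites, config)
            path = out / "flux.csv"
            flux.to_csv(path)
            manifest.outputs["flux"] = str(path)

        elif stage == "connectivity":
            if flux is None:
                if "flux" not in params:
                    raise ValueError("connectivity stage needs a flux table "
                                     "(run dispersal or give 'flux')")
                flux = FluxTable.from_csv(params["flux"])
            norm = params.get("normalization", "actual")
            effectiveness(flux, norm).to_csv(out / "effectiveness.csv")
            if len(flux.years) >= 2:
                persistence(flux).to_csv(out / "persistence.csv", percent=False)
                trends = interannual_trends(flux)
                (out / "trends.json").write_text(json.dumps(trends, indent=2))
            rate_decomposition(flux).to_csv(out / "rates.csv")
            manifest.outputs["connectivity"] = str(out)

        elif stage == "synth_genotypes":
            gp = SyntheticGenotypeParams(seed=seed, **params)
            dataset = simulate_genotype_dataset(gp)
            path = out / "genotypes.gen"
            write_genepop(dataset, path)
            manifest.outputs["genotypes"] = str(path)

        elif stage == "popgen":
            if dataset is None:
                if "genepop" not in params:
                    raise ValueError("popgen stage needs genotypes "
                                     "(run synth_genotypes or give 'genepop')")
                dataset = read_genepop(params["genepop"])
            filtered = apply_standard_filters(dataset)
            n_perm = int(params.get("n_permutations", 999))
            diversity_table(filtered).to_csv(out / "diversity.csv")
            pairwise_fst(filtered, n_permutations=n_perm,
                         seed=seed).to_csv(out / "pairwise_fst.csv")
            res = wc_theta(filtered, n_permutations=n_perm, seed=seed)
            am = amova(filtered, n_permutations=min(n_perm, 200), seed=seed)
            report = {
                "global_theta": res.theta, "theta_p": res.p_value,
                "theta_ci": res.ci, "f_st": am.f_st,
                "percent_variation": am.percent_variation,
                "n_loci": filtered.n_loci,
                "n_individuals": filtered.n_individuals,
            }
            if params.get("scan_partitions", False):
                table = scan_partitions(filtered)
                table.drop(columns="groups").to_csv(out / "partitions.csv",
                                                    index=False)
                report["best_partition"] = table.iloc[0]["partition"]
            (out / "popgen.json").write_text(json.dumps(report, indent=2))
            manifest.outputs["popgen"] = str(out / "popgen.json")

        elif stage == "forward_sim":
            freqs = params.get("initial_frequencies")
            if freqs is None:
                sub = np.random.default_rng(seed)
                freqs = 0.5 * sub.beta(1.2, 3.0, size=int(params.get("n_loci", 1122)))
            model = ForwardModel(
                n_demes=int(params.get("n_demes", 8)),
                deme_size=int(params.get("deme_size", 400)),
                marker_type=params.get("marker_type", "biallelic_diploid"),
                initial_frequencies=np.asarray(freqs, dtype=float),
                mutation_rate=float(params.get("mutation_rate", 0.0)),
                migrants_per_generation=float(params.get("migrants", 0.0)),
                sample_sizes=tuple(params.get("sample_sizes",
                                              (31, 30, 25, 26, 28, 31, 30, 29))),
            )
            t = int(params.get("generations", 2))
            reps = int(params.get("replicates", 200))
            mean_fst, se = simulate_drift_fst(model, t, replicates=reps, rng=seed)
            power = powsim_power(model, t, replicates=reps, rng=seed + 1)
            result = {"mean_fst": mean_fst, "mc_se": se,
                      "power": power.power, "generations": t,
                      "deme_size": model.deme_size}
            (out / "forward.json").write_text(json.dumps(result, indent=2))
            manifest.outputs["forward"] = str(out / "forward.json")

        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)

    manifest.write(out / "manifest.json")
    return manifest
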