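"""Readers and writers for the tab-separated and YAML interchange formats.

All tabular formats are UTF-8, tab-separated with a mandatory header row;
``.`` marks a missing value.  States, alleles, haplotypes and diplotypes
use the canonical text dialect of :mod:`phasecnv.sites` (``-`` deletion,
``,`` copy-unit separator, ``_`` site separator, ``/`` haplotype
separator).  Every writer's output is re-readable by the matching reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .calling import DiplotypeCall
from .em import FrequencyTable
from .likelihood import GaussianComponent, GenoSpectrum, SignalModel
from .metrics import EvaluationReport
from .sites import (
    Diplotype,
    SiteSpec,
    SiteType,
    State,
    collapse_diplotype,
    parse_diplotype,
    parse_haplotype,
    parse_state,
    state_to_str,
)

__all__ = [
    "FileFormatError",
    "read_sites",
    "write_sites",
    "read_spectra",
    "write_spectra",
    "read_signal_model",
    "write_signal_model",
    "read_intensities",
    "write_intensities",
    "read_frequencies",
    "write_frequencies",
    "read_truth",
    "write_truth",
    "read_diplotype_calls",
    "write_diplotype_calls",
    "write_report",
    "read_sim_config",
]

MISSING = "."


class FileFormatError(ValueError):
    """A malformed input file; carries the file and (1-based) line number."""

    def __init__(self, path, line: Optional[int], message: str) -> None:
        where = f"{path}" + (f", line {line}" if line is not None else "")
        super().__init__(f"{where}: {message}")
        self.path = path
        self.line = line


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FileFormatError(path, None, f"cannot parse TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FileFormatError(path, 1, f"missing required column(s): {', '.join(missing)}")
    return df


def _row_line(i: int) -> int:
    return i + 2  # header is line 1


def read_sites(path) -> Tuple[SiteSpec, ...]:
    """Read site specifications (columns: site_id, site_type, alphabet,
    max_total_copies, max_allele_copies)."""
    df = _read_tsv(path, ["site_id", "site_type", "alphabet", "max_total_copies", "max_allele_copies"])
    sites: List[SiteSpec] = []
    for i, row in df.iterrows():
        try:
            alphabet = row["alphabet"]
            symbols = () if alphabet in ("", MISSING) else tuple(alphabet.split(","))
            sites.append(
                SiteSpec(
                    site_id=row["site_id"],
                    site_type=SiteType(row["site_type"]),
                    alphabet=symbols,
                    max_total_copies=int(row["max_total_copies"]),
                    max_allele_copies=int(row["max_allele_copies"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise FileFormatError(path, _row_line(i), str(exc)) from exc
    if not sites:
        raise FileFormatError(path, None, "no sites defined")
    if len({s.site_id for s in sites}) != len(sites):
        raise FileFormatError(path, None, "duplicate site_id")
    return tuple(sites)


def write_sites(path, sites: Sequence[SiteSpec]) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "site_type": s.site_type.value,
            "alphabet": ",".join(s.alphabet) if s.alphabet else MISSING,
            "max_total_copies": s.max_total_copies,
            "max_allele_copies": s.max_allele_copies,
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spectra(path, sites: Sequence[SiteSpec]) -> GenoSpectrum:
    """Read likelihood tables (columns: individual_id, site_id, state,
    likelihood).  Missing (individual, site) pairs become missing calls."""
    df = _read_tsv(path, ["individual_id", "site_id", "state", "likelihood"])
    by_id = {s.site_id: s for s in sites}
    tables: Dict[str, Dict[str, Dict[State, float]]] = {}
    for i, row in df.iterrows():
        site = by_id.get(row["site_id"])
        if site is None:
            raise FileFormatError(path, _row_line(i), f"unknown site_id {row['site_id']!r}")
        try:
            state = parse_state(row["state"], site)
            lik = float(row["likelihood"])
            if not np.isfinite(lik) or lik < 0:
                raise ValueError(f"bad likelihood {row['likelihood']!r}")
        except ValueError as exc:
            raise FileFormatError(path, _row_line(i), str(exc)) from exc
        table = tables.setdefault(row["individual_id"], {}).setdefault(site.site_id, {})
        if state in table:
            raise FileFormatError(
                path, _row_line(i),
                f"duplicate state {row['state']!r} for individual {row['individual_id']!r}",
            )
        table[state] = lik
    if not tables:
        raise FileFormatError(path, None, "no spectrum rows")
    return GenoSpectrum(tables, sites)


def write_spectra(path, spectra: GenoSpectrum) -> None:
    rows = []
    for ind, per_site in spectra.tables.items():
        for site in spectra.sites:
            table = per_site.get(site.site_id)
            if table is None:
                continue
            for state in sorted(table, key=lambda s: state_to_str(s, site)):
                rows.append(
                    {
                        "individual_id": ind,
                        "site_id": site.site_id,
                        "state": state_to_str(state, site),
                        "likelihood": repr(table[state]),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_floats(text: str, path, line: int) -> np.ndarray:
    try:
        return np.array([float(v) for v in text.split(",")])
    except ValueError as exc:
        raise FileFormatError(path, line, f"bad numeric list {text!r}") from exc


def read_signal_model(path, sites: Sequence[SiteSpec]) -> SignalModel:
    """Read a Gaussian cluster model from TSV (site_id, state, mean,
    covariance; comma-joined numbers, covariance row-major) or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        return _signal_model_from_yaml(path, sites)
    df = _read_tsv(path, ["site_id", "state", "mean", "covariance"])
    by_id = {s.site_id: s for s in sites}
    components: Dict[str, Dict[State, GaussianComponent]] = {}
    for i, row in df.iterrows():
        site = by_id.get(row["site_id"])
        if site is None:
            raise FileFormatError(path, _row_line(i), f"unknown site_id {row['site_id']!r}")
        try:
            state = parse_state(row["state"], site)
        except ValueError as exc:
            raise FileFormatError(path, _row_line(i), str(exc)) from exc
        mean = _parse_floats(row["mean"], path, _row_line(i))
        cov_flat = _parse_floats(row["covariance"], path, _row_line(i))
        if cov_flat.size == mean.size * mean.size:
            cov = cov_flat.reshape(mean.size, mean.size)
        elif cov_flat.size == 1:
            cov = float(cov_flat[0]) * np.eye(mean.size)
        else:
            raise FileFormatError(
                path, _row_line(i),
                f"covariance has {cov_flat.size} entries for a {mean.size}-dimensional mean",
            )
        try:
            components.setdefault(site.site_id, {})[state] = GaussianComponent(mean, cov)
        except ValueError as exc:
            raise FileFormatError(path, _row_line(i), str(exc)) from exc
    return SignalModel(components)


def _signal_model_from_yaml(path: Path, sites: Sequence[SiteSpec]) -> SignalModel:
    data = yaml.safe_load(path.read_text())
    by_id = {s.site_id: s for s in sites}
    components: Dict[str, Dict[State, GaussianComponent]] = {}
    try:
        for site_id, states in data.items():
            site = by_id[site_id]
            for state_text, comp in states.items():
                state = parse_state(str(state_text), site)
                components.setdefault(site_id, {})[state] = GaussianComponent(
                    np.atleast_1d(np.asarray(comp["mean"], dtype=float)),
                    np.asarray(comp["covariance"], dtype=float),
                )
    except (KeyError, TypeError, ValueError) as exc:
        raise FileFormatError(path, None, f"bad signal model YAML: {exc}") from exc
    return SignalModel(components)


def write_signal_model(path, model: SignalModel, sites: Sequence[SiteSpec]) -> None:
    by_id = {s.site_id: s for s in sites}
    rows = []
    for site_id, comps in model.components.items():
        site = by_id[site_id]
        for state, comp in comps.items():
            rows.append(
                {
                    "site_id": site_id,
                    "state": state_to_str(state, site),
                    "mean": ",".join(repr(float(v)) for v in comp.mean),
                    "covariance": ",".join(repr(float(v)) for v in comp.cov.ravel()),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_intensities(path, sites: Sequence[SiteSpec]) -> Tuple[List[str], Dict[str, np.ndarray]]:
    """Read raw measurements (individual_id, site_id, value with comma-joined
    channels).  Returns the individual order and per-site arrays."""
    df = _read_tsv(path, ["individual_id", "site_id", "value"])
    by_id = {s.site_id: s for s in sites}
    values: Dict[str, Dict[str, np.ndarray]] = {}
    order: List[str] = []
    for i, row in df.iterrows():
        if row["site_id"] not in by_id:
            raise FileFormatError(path, _row_line(i), f"unknown site_id {row['site_id']!r}")
        ind = row["individual_id"]
        if ind not in values:
            values[ind] = {}
            order.append(ind)
        values[ind][row["site_id"]] = _parse_floats(row["value"], path, _row_line(i))
    measurements: Dict[str, np.ndarray] = {}
    for site in sites:
        per_ind = []
        for ind in order:
            if site.site_id not in values[ind]:
                raise FileFormatError(
                    path, None, f"individual {ind!r} has no measurement at site {site.site_id!r}"
                )
            per_ind.append(values[ind][site.site_id])
        measurements[site.site_id] = np.vstack(per_ind)
    return order, measurements


def write_intensities(path, individuals: Sequence[str], measurements: Mapping[str, np.ndarray]) -> None:
    rows = []
    for site_id, x in measurements.items():
        for i, ind in enumerate(individuals):
            rows.append(
                {
                    "individual_id": ind,
                    "site_id": site_id,
                    "value": ",".join(repr(float(v)) for v in np.atleast_1d(x[i])),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_frequencies(path, sites: Sequence[SiteSpec]) -> FrequencyTable:
    df = _read_tsv(path, ["haplotype", "frequency"])
    table = FrequencyTable()
    for i, row in df.iterrows():
        try:
            hap = parse_haplotype(row["haplotype"], sites)
            table[hap] = float(row["frequency"])
        except ValueError as exc:
            raise FileFormatError(path, _row_line(i), str(exc)) from exc
    if not table:
        raise FileFormatError(path, None, "no frequency rows")
    return table


def write_frequencies(path, freqs: FrequencyTable) -> None:
    rows = [
        {"haplotype": str(h), "frequency": repr(v)} for h, v in freqs.sorted_items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path, sites: Sequence[SiteSpec]) -> Dict[str, Diplotype]:
    df = _read_tsv(path, ["individual_id", "diplotype"])
    out: Dict[str, Diplotype] = {}
    for i, row in df.iterrows():
        try:
            out[row["individual_id"]] = parse_diplotype(row["diplotype"], sites)
        except ValueError as exc:
            raise FileFormatError(path, _row_line(i), str(exc)) from exc
    if not out:
        raise FileFormatError(path, None, "no truth rows")
    return out


def write_truth(path, truth: Mapping[str, Diplotype]) -> None:
    rows = [{"individual_id": ind, "diplotype": str(d)} for ind, d in truth.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_diplotype_calls(
    path,
    calls: Mapping[str, DiplotypeCall],
    sites: Sequence[SiteSpec],
) -> None:
    """Write calls with per-site implied unphased states (``.`` for no-calls)."""
    rows = []
    for ind, call in calls.items():
        row = {
            "individual_id": ind,
            "diplotype": MISSING if call.is_no_call else str(call.diplotype),
            "proportion": repr(call.proportion),
        }
        states = (
            None if call.is_no_call else collapse_diplotype(call.diplotype, sites)
        )
        for s, site in enumerate(sites):
            row[f"state_{site.site_id}"] = (
                MISSING if states is None else state_to_str(states[s], site)
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_diplotype_calls(path, sites: Sequence[SiteSpec]) -> Dict[str, DiplotypeCall]:
    df = _read_tsv(path, ["individual_id", "diplotype", "proportion"])
    out: Dict[str, DiplotypeCall] = {}
    for i, row in df.iterrows():
        try:
            diplotype = (
                None if row["diplotype"] == MISSING else parse_diplotype(row["diplotype"], sites)
            )
            out[row["individual_id"]] = DiplotypeCall(diplotype, float(row["proportion"]))
        except ValueError as exc:
            raise FileFormatError(path, _row_line(i), str(exc)) from exc
    if not out:
        raise FileFormatError(path, None, "no diplotype rows")
    return out


def write_report(path, reports: Sequence[EvaluationReport], labels: Optional[Sequence] = None) -> None:
    """Write one row per replicate plus mean and SD aggregate rows."""
    if not reports:
        raise ValueError("no reports to write")
    labels = list(labels) if labels is not None else list(range(len(reports)))
    df = pd.DataFrame([r.to_dict() for r in reports])
    df.insert(0, "replicate", [str(l) for l in labels])
    metric_cols = [c for c in df.columns if c != "replicate"]
    mean_row = {"replicate": "mean", **{c: df[c].mean() for c in metric_cols}}
    sd_row = {"replicate": "sd", **{c: df[c].std(ddof=1) if len(df) > 1 else 0.0 for c in metric_cols}}
    out = pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)
    out.to_csv(path, sep="\t", index=False)


def read_sim_config(path):
    """Read a simulation configuration from YAML.

    Schema::

        n_individuals: 588
        n_replicates: 14
        seed: 0
        sites: [{site_id, site_type, alphabet, max_total_copies,
                 max_allele_copies}, ...]
        frequencies: {haplotype string: frequency, ...}
        noise:
          spacing: 1.0
          sd: 0.4              # or null with a target_miscall_rate
          target_miscall_rate: 0.22
    """
    from .simulate import SimConfig  # local import to avoid cycle

    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
        sites = tuple(
            SiteSpec(
                site_id=s["site_id"],
                site_type=SiteType(s["site_type"]),
                alphabet=tuple(s.get("alphabet") or ()),
                max_total_copies=int(s.get("max_total_copies", 4)),
                max_allele_copies=int(s.get("max_allele_copies", 2)),
            )
            for s in data["sites"]
        )
        freqs = FrequencyTable.from_strings(
            {str(k): float(v) for k, v in data["frequencies"].items()}, sites
        )
        noise = data.get("noise") or {}
        return SimConfig(
            sites=sites,
            frequencies=freqs,
            n_individuals=int(data["n_individuals"]),
            spacing=float(noise.get("spacing", 1.0)),
            sd=noise.get("sd"),
            target_miscall_rate=noise.get("target_miscall_rate"),
            n_replicates=int(data.get("n_replicates", 1)),
            seed=int(data.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FileFormatError(path, None, f"bad simulation config: {exc}") from exc
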