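"""Plain-text I/O: cohort CSV + JSON sidecar, and report writing.

All tabular outputs are CSV (missing cells empty, dot-decimal) and all
structured outputs JSON with sorted keys, so two runs from the same seed
produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, GroupSpec, SyntheticCohort
from .preprocessing import GroupMap

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_json",
    "read_json",
    "group_map_to_dict",
    "group_map_from_dict",
]


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def group_map_to_dict(gm: GroupMap) -> dict:
    # group order is meaningful; serialize as ordered pair-lists so JSON
    # key-sorting cannot scramble it
    return {
        "entries": [[g, cols] for g, cols in gm.entries.items()],
        "reduced_entries": (
            [[g, cols] for g, cols in gm.reduced_entries.items()]
            if gm.reduced_entries is not None
            else None
        ),
    }


def group_map_from_dict(obj: dict) -> GroupMap:
    return GroupMap(
        entries={g: list(c) for g, c in obj["entries"]},
        reduced_entries=(
            {g: list(c) for g, c in obj["reduced_entries"]}
            if obj.get("reduced_entries")
            else None
        ),
    )


def write_cohort(cohort: SyntheticCohort, csv_path: str | Path, meta_path: str | Path) -> None:
    """Cohort table as CSV (MoCA outcome columns appended) plus a JSON sidecar
    with group membership, spec, and planted ground truth."""
    csv_path, meta_path = Path(csv_path), Path(meta_path)
    table = cohort.X_raw.copy()
    table["moca_baseline"] = cohort.moca_baseline
    table["moca_followup"] = cohort.moca_followup
    table.to_csv(csv_path, index=False, float_format="%.17g")
    spec = cohort.spec
    meta = {
        "groups": [[g, cols] for g, cols in cohort.group_map.entries.items()],
        "truth_informative": sorted(cohort.truth_informative),
        "seed": spec.seed,
        "spec": {
            "n_subjects": spec.n_subjects,
            "target_prevalence_followup": spec.target_prevalence_followup,
            "target_prevalence_baseline": spec.target_prevalence_baseline,
            "missing_rate": spec.missing_rate,
            "noise_sd": spec.noise_sd,
            "groups": [
                {
                    "name": g.name,
                    "n_vars": g.n_vars,
                    "block_correlation": g.block_correlation,
                    "informative": g.informative,
                    "effect_size": g.effect_size,
                }
                for g in spec.groups
            ],
        },
    }
    write_json(meta_path, meta)


def _check_header(path: Path) -> list[str]:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicated column name(s) in {path}: {sorted(dupes)}")
    return header


def read_cohort(csv_path: str | Path, meta_path: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`.

    Empty cells parse as missing; non-numeric cells raise with coordinates.
    """
    csv_path, meta_path = Path(csv_path), Path(meta_path)
    header = _check_header(csv_path)
    table = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    cols: dict[str, pd.Series] = {}
    for col in header:
        raw = table[col].replace("", np.nan)
        try:
            cols[col] = pd.to_numeric(raw)
        except (ValueError, TypeError):
            bad = raw[pd.to_numeric(raw, errors="coerce").isna() & raw.notna()]
            row = int(bad.index[0])
            raise ValueError(
                f"non-numeric cell at row {row}, column {col!r}: {bad.iloc[0]!r}"
            ) from None
    numeric = pd.DataFrame(cols)

    meta = read_json(meta_path)
    spec_obj = meta["spec"]
    spec = CohortSpec(
        n_subjects=spec_obj["n_subjects"],
        groups=tuple(
            GroupSpec(
                name=g["name"],
                n_vars=g["n_vars"],
                block_correlation=g["block_correlation"],
                informative=g["informative"],
                effect_size=g["effect_size"],
            )
            for g in spec_obj["groups"]
        ),
        target_prevalence_followup=spec_obj["target_prevalence_followup"],
        target_prevalence_baseline=spec_obj["target_prevalence_baseline"],
        missing_rate=spec_obj["missing_rate"],
        noise_sd=spec_obj["noise_sd"],
        seed=meta["seed"],
    )
    gm = GroupMap(entries={g: list(c) for g, c in meta["groups"]})
    feature_cols = [c for cols in gm.entries.values() for c in cols]
    return SyntheticCohort(
        X_raw=numeric[feature_cols].astype(float),
        group_map=gm,
        moca_baseline=numeric["moca_baseline"].to_numpy(dtype=int),
        moca_followup=numeric["moca_followup"].to_numpy(dtype=int),
        latent_factors=pd.DataFrame(),
        truth_informative=frozenset(meta["truth_informative"]),
        spec=spec,
    )
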