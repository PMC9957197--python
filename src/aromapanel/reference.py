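"""Packaged reference tables for the three-region peach volatile study.

Two small tables are shipped with the package:

* compound metadata for the 23 volatiles identified across the Beijing (BJ),
  Shandong (SD) and Hebei (HB) cultivation regions — retention time,
  calculated and library Kovats retention indices, literature odor threshold
  in water (µg/L; ``n.f`` where no value exists) and chemical class;
* the published per-region concentration summaries (mean ± SD, µg/kg,
  ``nd`` = not detected) that parameterize the synthetic sample generator.

Both are stored as plain CSV text so they remain human-auditable.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .data import CompoundMeta, FeatureTable, _parse_optional_float

__all__ = [
    "REGIONS",
    "packaged_compound_meta",
    "packaged_region_params",
    "region_mean_table",
]

#: Region labels of the packaged study, in lexicographic order.
REGIONS = ("BJ", "HB", "SD")

# name, RT (min), RI calc, RI lib, odor description, threshold µg/L, category
_COMPOUND_CSV = """\
name;retention_time;ri_calc;ri_lib;description;threshold;category
Isocyanic acid;4.47;;;/;n.f;acid
Methyl acetate;4.93;;;sweet, fruity;3;ester
2-Methylpropane;5.97;605;;/;n.f;hydrocarbon
Pentan-3-one;6.45;703;700;ethereal acetone;40;ketone
2-Butan-2-yloxybutane;8.39;801;;/;n.f;ether
1-(Furan-2-yl)pentan-1-one;8.73;815;;/;n.f;ketone
(E)-Hex-2-enal;9.72;858;854;green, leaf;30;aldehyde
5-Methylhept-3-yne;9.77;860;;/;n.f;hydrocarbon
Ethylbenzene;9.85;863;864;/;1200;benzene
1,2-Xylene;10.18;877;;geranium;450;benzene
Methyl hexanoate;11.24;922;924;fruity;70;ester
Benzaldehyde;12.42;970;970;sweet;750;aldehyde
(2R)-2-Hydroxy-3-methylbutanenitrile;12.66;980;;/;n.f;alcohol
[(Z)-Hex-3-enyl] acetate;13.25;1004;1009;green, leaf;8;ester
Hexyl acetate;13.40;1011;1010;fruity;10;ester
(Z)-Hex-2-enyl acetate;13.45;1013;1005;/;n.f;ester
(E)-Hex-3-en-1-yne;13.75;1025;;/;n.f;hydrocarbon
Phenylmethanol;14.27;1047;1042;floral, rose;2500;alcohol
5-Ethyloxolan-2-one;14.49;1056;1056;sweet, coconut;50;lactone
Octan-1-ol;14.85;1071;1068;green;130;alcohol
Nonan-1-ol;17.19;1171;1172;floral rose;50;alcohol
[(E)-Hex-2-enyl] 3-methylbutanoate;18.79;1242;1244;/;n.f;ester
2,3-Dimethylbut-3-en-2-ol;21.43;1366;;/;n.f;alcohol
"""

# Per-region concentration mean ± SD in µg/kg; "nd" = not detected.
_REGION_CSV = """\
name;BJ_mean;BJ_sd;SD_mean;SD_sd;HB_mean;HB_sd
Isocyanic acid;51.92;6.52;87.67;5.35;92.08;7.68
Methyl acetate;123.67;12.57;602.58;86.40;97.50;8.99
2-Methylpropane;4.83;0.83;nd;nd;nd;nd
Pentan-3-one;13.17;1.70;nd;nd;nd;nd
2-Butan-2-yloxybutane;129.67;11.48;116.92;23.45;188.00;10.82
1-(Furan-2-yl)pentan-1-one;3.67;0.98;14.00;1.86;6.08;1.62
(E)-Hex-2-enal;606.17;52.16;2688.33;331.83;65.75;8.85
5-Methylhept-3-yne;nd;nd;5.33;1.15;nd;nd
Ethylbenzene;166.08;15.37;87.00;7.83;88.83;7.32
1,2-Xylene;264.67;35.01;339.33;46.64;425.92;16.56
Methyl hexanoate;nd;nd;nd;nd;45.00;7.77
Benzaldehyde;1546.42;203.31;4858.00;178.88;3628.92;266.85
(2R)-2-Hydroxy-3-methylbutanenitrile;nd;nd;nd;nd;12.08;1.62
[(Z)-Hex-3-enyl] acetate;1567.83;248.83;482.25;95.83;524.58;98.45
Hexyl acetate;1915.08;161.47;2290.92;144.76;1782.25;294.10
(Z)-Hex-2-enyl acetate;1821.17;185.55;1826.42;161.33;1592.25;308.70
(E)-Hex-3-en-1-yne;7.67;1.56;nd;nd;nd;nd
Phenylmethanol;nd;nd;196.42;12.44;nd;nd
5-Ethyloxolan-2-one;135.50;32.10;11.92;3.29;384.83;45.06
Octan-1-ol;35.67;8.97;nd;nd;nd;nd
Nonan-1-ol;143.42;26.49;44.58;6.29;38.17;10.31
[(E)-Hex-2-enyl] 3-methylbutanoate;nd;nd;28.00;3.30;nd;nd
2,3-Dimethylbut-3-en-2-ol;nd;nd;15.42;2.61;nd;nd
"""


def packaged_compound_meta() -> list[CompoundMeta]:
    """The 23 packaged compound annotations, in elution order."""
    df = pd.read_csv(io.StringIO(_COMPOUND_CSV), sep=";", dtype=str,
                     keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        desc = row["description"].strip()
        out.append(CompoundMeta(
            name=row["name"],
            retention_time=float(row["retention_time"]),
            retention_index_calc=_parse_optional_float(row["ri_calc"]),
            retention_index_lib=_parse_optional_float(row["ri_lib"]),
            odor_threshold=_parse_optional_float(row["threshold"]),
            odor_description=None if desc == "/" else desc,
            category=row["category"],
        ))
    return out


def packaged_region_params() -> pd.DataFrame:
    """Long-form per-cell generator parameters.

    Columns: ``region``, ``compound``, ``mean``, ``sd`` (µg/kg) and
    ``detected``; not-detected cells carry mean = sd = 0.
    """
    df = pd.read_csv(io.StringIO(_REGION_CSV), sep=";", dtype=str,
                     keep_default_na=False)
    rows = []
    for _, row in df.iterrows():
        for region in REGIONS:
            m, s = row[f"{region}_mean"], row[f"{region}_sd"]
            detected = m != "nd"
            rows.append({
                "region": region,
                "compound": row["name"],
                "mean": float(m) if detected else 0.0,
                "sd": float(s) if detected else 0.0,
                "detected": detected,
            })
    return pd.DataFrame(rows)


def region_mean_table() -> FeatureTable:
    """The published region means as a 3-sample feature table.

    One row per region holding that region's mean concentrations; used for
    desk-checking odor-activity values against the published OAV table.
    """
    params = packaged_region_params()
    metas = packaged_compound_meta()
    names = [c.name for c in metas]
    values = np.zeros((len(REGIONS), len(names)))
    nd = np.zeros_like(values, dtype=bool)
    for i, region in enumerate(REGIONS):
        sub = params[params.region == region].set_index("compound")
        for j, name in enumerate(names):
            values[i, j] = sub.loc[name, "mean"]
            nd[i, j] = not sub.loc[name, "detected"]
    return FeatureTable(
        sample_ids=[f"{r}_mean" for r in REGIONS],
        region_labels=list(REGIONS),
        compounds=metas,
        values=values,
        nd_mask=nd,
    )
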