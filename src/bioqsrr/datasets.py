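"""Packaged reference data: the 18-organophosphate chromatographic
index table and the three published QSRR reference models.

The index table carries four measured endpoints per compound:
CHI_C18 (C18 lipophilicity index), CHI_IAM (phospholipid-affinity
index), LogK_HSA (log albumin affinity) and %HSA (percent plasma-
protein binding).  LogK_HSA and %HSA are stored as independently
printed columns; the logistic relation between them lives in
:mod:`bioqsrr.chrom_indices`.
"""

from __future__ import annotations

from .datatypes import CompoundRecord, QSRRModel, RetentionTable

__all__ = ["organophosphate_table", "reference_models", "descriptor_metadata"]

# id, name, chi_c18, chi_iam, logk_hsa, pct_hsa
_OP_ROWS = [
    (1, "Azinphos-ethyl", 95.69, 37.81, 1.01, 92.07),
    (2, "Azinphos-methyl", 83.47, 33.18, 0.78, 86.70),
    (3, "Chlorfenvinphos", 97.18, 38.13, 0.74, 85.54),
    (4, "Chlorpyrifos-oxon", 39.17, 24.96, 0.68, 83.49),
    (5, "Diazinon", 105.98, 39.34, 0.62, 81.33),
    (6, "Dichlorvos", 23.17, 16.56, 0.27, 65.86),
    (7, "Disulfoton", 108.97, 42.34, 1.06, 92.86),
    (8, "Ethoprophos", 88.39, 32.41, -0.41, 28.35),
    (9, "Fenitrothion", 93.49, 38.10, 1.00, 91.78),
    (10, "Fenthion", 102.16, 42.37, 1.29, 96.04),
    (11, "Mecarbam", 97.09, 35.77, 0.44, 74.23),
    (12, "Naled", 31.32, 29.79, -0.11, 43.86),
    (13, "Paraoxon-ethyl", 72.54, 25.34, -0.42, 27.68),
    (14, "Parathion-methyl", 88.75, 35.54, 0.83, 87.94),
    (15, "Phorate", 108.36, 42.43, 1.07, 93.08),
    (16, "Phosmet", 85.39, 33.89, 0.80, 87.23),
    (17, "Quinalphos", 101.01, 39.40, 0.97, 91.23),
    (18, "Triazophos", 92.96, 38.08, 0.74, 85.43),
]


def organophosphate_table() -> RetentionTable:
    """The packaged 18-compound organophosphate index table."""
    return RetentionTable(CompoundRecord(*row) for row in _OP_ROWS)


# published model equations with their validation statistics
_REFERENCE_MODELS = [
    dict(
        endpoint_name="chi_c18",
        intercept=82.496,
        coefficients={"SpMax_Dz(i)": 17.488, "R3s": -17.080},
        stats=dict(
            r2_tr=0.870, rmse_tr=6.889, q2_loo=0.894, rmse_loo=8.622,
            r2_ext=0.696, rmse_p=12.552, ccc_ext=0.833,
        ),
    ),
    dict(
        endpoint_name="chi_iam",
        intercept=34.273,
        coefficients={"LogP": 4.836, "PJI3": 3.392},
        stats=dict(
            r2_tr=0.914, rmse_tr=2.008, q2_loo=0.855, rmse_loo=2.735,
            r2_ext=0.880, rmse_p=1.884, ccc_ext=0.955,
        ),
    ),
    dict(
        endpoint_name="logk_hsa",
        intercept=0.600,
        coefficients={"LogS": -0.423, "TDB05i": -0.284},
        stats=dict(
            r2_tr=0.844, rmse_tr=0.217, q2_loo=0.576, rmse_loo=0.340,
            r2_ext=0.898, rmse_p=0.125, ccc_ext=0.960,
        ),
    ),
]

# descriptor provenance: full name, block, software
_DESCRIPTOR_META = {
    "SpMax_Dz(i)": dict(
        description="Leading eigenvalue from Barysz matrix weighted by ionization potential",
        block="2D matrix-based descriptors", software="alvaDesc",
    ),
    "R3s": dict(
        description="R autocorrelation of lag 3 / weighted by I-state",
        block="GETAWAY descriptors", software="alvaDesc",
    ),
    "LogP": dict(
        description="Logarithm of the octanol/water partition coefficient",
        block="Physicochemical properties", software="Chemicalize",
    ),
    "PJI3": dict(
        description="3D Petitjean shape index",
        block="Geometrical descriptors", software="alvaDesc",
    ),
    "LogS": dict(
        description="Intrinsic solubility",
        block="Physicochemical properties", software="Chemicalize",
    ),
    "TDB05i": dict(
        description="Topological distance-based descriptor, lag 5 weighted by ionization potential",
        block="3D autocorrelations", software="alvaDesc",
    ),
}


def reference_models() -> list[QSRRModel]:
    """The three published two-descriptor reference models.

    Returned with the printed validation statistics in ``fit_meta["stats"]``;
    these models carry no training data (the underlying descriptor values
    were computed by external software and are not distributed).
    """
    return [
        QSRRModel(
            endpoint_name=m["endpoint_name"],
            intercept=m["intercept"],
            coefficients=dict(m["coefficients"]),
            fit_meta={"source": "published reference", "stats": dict(m["stats"])},
        )
        for m in _REFERENCE_MODELS
    ]


def descriptor_metadata() -> dict[str, dict[str, str]]:
    """Provenance for the six descriptors used by the reference models."""
    return {k: dict(v) for k, v in _DESCRIPTOR_META.items()}
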