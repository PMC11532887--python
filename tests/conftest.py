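import numpy as np
import pytest

from symnet import BinarySymptomMatrix, IsingNetwork, SymptomCatalog

# Reference per-symptom occurrence counts: (name, code, total count,
# printed total %, group-a count, printed a %, group-b count, printed b %).
# Group sizes: a = 6391, b = 555 (total 6946).
REFERENCE_OCCURRENCE = [
    ("Weight loss", "S1", 6600, 95.02, 6096, 95.38, 504, 90.81),
    ("Insomnia", "S2", 4110, 59.17, 3804, 59.52, 306, 55.14),
    ("Edema", "S3", 1843, 26.53, 1778, 27.82, 65, 11.71),
    ("Excessive sweating", "S4", 1039, 14.96, 976, 15.27, 63, 11.35),
    ("Loss of appetite", "S5", 4309, 62.04, 4007, 62.70, 302, 54.41),
    ("Hiccups", "S6", 396, 5.70, 380, 5.95, 16, 2.88),
    ("Reflux/belching", "S7", 509, 7.33, 486, 7.60, 23, 4.14),
    ("Swallowing obstruction", "S8", 787, 11.33, 760, 11.89, 27, 4.86),
    ("Nausea", "S9", 2298, 33.08, 2180, 34.11, 118, 21.26),
    ("Vomiting", "S10", 2200, 31.67, 2070, 32.39, 130, 23.42),
    ("Constipation", "S11", 3431, 49.40, 3205, 50.15, 226, 40.72),
    ("Abdominal distension", "S12", 2213, 31.86, 2110, 33.02, 103, 18.56),
    ("Stomachache", "S13", 3416, 49.18, 3220, 50.38, 196, 35.32),
    ("Gastrointestinal bleeding", "S14", 224, 3.22, 213, 3.33, 11, 1.98),
    ("Cough", "S15", 2091, 30.10, 1941, 30.37, 150, 27.03),
    ("Coughing up sputum", "S16", 1435, 20.66, 1355, 21.20, 80, 14.41),
    ("Gasping", "S17", 704, 10.14, 657, 10.28, 47, 8.47),
    ("Chest pain", "S18", 1610, 23.18, 1477, 23.11, 133, 23.96),
    ("Hemoptysis", "S19", 309, 4.45, 288, 4.51, 21, 3.78),
    ("Chest tightness", "S20", 1028, 14.80, 955, 14.94, 73, 13.15),
    ("Palpitation", "S21", 257, 3.70, 241, 3.77, 16, 2.88),
    ("Orthopnea", "S22", 87, 1.25, 79, 1.24, 8, 1.44),
    ("Dysuria", "S23", 236, 3.40, 214, 3.35, 22, 3.96),
    ("Urinary incontinence", "S24", 160, 2.30, 151, 2.36, 9, 1.62),
    ("Oliguria", "S25", 301, 4.33, 292, 4.57, 9, 1.62),
    ("Arthralgia", "S26", 889, 12.80, 808, 12.64, 81, 14.59),
    ("Dizziness", "S27", 1443, 20.77, 1343, 21.01, 100, 18.02),
    ("Headache", "S28", 1022, 14.71, 952, 14.90, 70, 12.61),
    ("Unsteady gait", "S29", 2127, 30.62, 1979, 30.97, 148, 26.67),
    ("Hearing loss", "S30", 487, 7.01, 437, 6.84, 50, 9.01),
    ("Vision loss", "S31", 267, 3.84, 246, 3.85, 21, 3.78),
    ("Impaired mobility", "S32", 434, 6.25, 423, 6.62, 11, 1.98),
    ("Malnutrition", "S33", 3862, 55.60, 3561, 55.72, 301, 54.23),
    ("Cachexia", "S34", 676, 9.73, 653, 10.22, 23, 4.14),
    ("Pleural effusion", "S35", 351, 5.05, 325, 5.09, 26, 4.68),
    ("Ascites", "S36", 633, 9.11, 620, 9.70, 13, 2.34),
]
GROUP_SIZES = {"lt6m": 6391, "6to12m": 555}


def catalog(p: int) -> SymptomCatalog:
    return SymptomCatalog(tuple(f"S{i + 1}" for i in range(p)))


def matrix_from_values(values, groups=None) -> BinarySymptomMatrix:
    values = np.asarray(values, dtype=np.int8)
    n, p = values.shape
    if groups is None:
        groups = np.full(n, "g", dtype=object)
    return BinarySymptomMatrix(values, catalog(p), np.asarray(groups, dtype=object))


def network_from_weights(weights, thresholds=None) -> IsingNetwork:
    w = np.asarray(weights, dtype=float)
    tau = np.zeros(w.shape[0]) if thresholds is None else np.asarray(thresholds, float)
    return IsingNetwork(w, tau, catalog(w.shape[0]))


def column_with_count(n: int, k: int) -> np.ndarray:
    """Deterministic binary column with exactly k ones."""
    col = np.zeros(n, dtype=np.int8)
    col[:k] = 1
    return col


def exact_boltzmann(tau, omega):
    """Brute-force joint distribution of a {0,1} pairwise binary MRF.

    Enumerates all 2^p states; weight of state x is
    exp(sum_i tau_i x_i + sum_{i<j} omega_ij x_i x_j).
    Returns (states array, probability vector).
    """
    tau = np.asarray(tau, float)
    omega = np.asarray(omega, float)
    p = len(tau)
    states = np.array(
        [[(s >> i) & 1 for i in range(p)] for s in range(2 ** p)], dtype=float
    )
    energy = states @ tau + 0.5 * np.einsum("si,ij,sj->s", states, omega, states)
    w = np.exp(energy)
    return states, w / w.sum()


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    return np.random.default_rng(20240301)
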