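"""Physical constants and element data shared across the toolkit.

Energies are kcal/mol, distances Å, temperatures K throughout.
"""

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

#: Coulomb conversion factor, kcal Å mol^-1 e^-2
COULOMB_KCAL = 332.0636

#: Consensus single-bond covalent radii, Å
COVALENT_RADII = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "CL": 1.02,
    "FE": 1.32,
    "ZN": 1.22,
    "MG": 1.41,
    "NA": 1.66,
    "K": 2.03,
}


def covalent_radius(element: str) -> float:
    """Look up the single-bond covalent radius of ``element`` in Å.

    Raises
    ------
    KeyError
        If the element is not in the table; the message names the element.
    """
    key = element.strip().upper()
    try:
        return COVALENT_RADII[key]
    except KeyError:
        raise KeyError(
            f"no covalent radius known for element {element!r}"
        ) from None
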