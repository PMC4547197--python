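"""Unit bridge between geometric lengths (µm) and optical coefficients (cm).

All specimen/camera geometry is expressed in micrometres; molecular cross
sections are cm², concentrations cm⁻³, attenuation/emission coefficients cm⁻¹
(the units in which fluorophore properties are tabulated).  Every µm↔cm
conversion in the package goes through this module so the factor is audited
in exactly one place.
"""

UM_PER_CM = 1.0e4
CM_PER_UM = 1.0e-4
CM2_PER_UM2 = 1.0e-8
CM3_PER_UM3 = 1.0e-12


def um_to_cm(length_um):
    """Convert a length (or array of lengths) from µm to cm."""
    return length_um * CM_PER_UM


def um2_to_cm2(area_um2):
    """Convert an area from µm² to cm²."""
    return area_um2 * CM2_PER_UM2


def um3_to_cm3(volume_um3):
    """Convert a volume from µm³ to cm³."""
    return volume_um3 * CM3_PER_UM3
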