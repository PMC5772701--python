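"""Write the bundled synthetic charged-particle spectra for the hydrogen and
photon dose components.

The reference fields' secondary spectra come from a macroscopic reactor-beam
simulation that is out of scope here; these simplified stand-ins keep the
hydrogen/photon pathways exercisable end-to-end.  Hydrogen: recoil protons
from elastic scattering of an epithermal-beam-like neutron spectrum (recoil
energy uniform per scatter, folded over a softened 1/E + fast tail), giving
weights ~ E^-0.7 exp(-E/0.8 MeV) on 0.01-3 MeV.  Photon: a Compton-like
secondary-electron continuum, weights ~ E^-0.3 exp(-E/0.35 MeV) on
0.003-1.5 MeV.
"""

import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "smkbnct" / "data"


def write(path, species, energy, weight, note):
    with open(path, "w") as fh:
        fh.write(f"# note={note}\n")
        fh.write("species\tenergy_MeV\tweight\n")
        for e, w in zip(energy, weight):
            fh.write(f"{species}\t{e:.6e}\t{w:.6e}\n")
    print("wrote", path)


def main():
    e_p = np.geomspace(0.01, 3.0, 40)
    w_p = e_p**-0.7 * np.exp(-e_p / 0.8)
    write(OUT / "spectrum_hydrogen_synthetic.tsv", "proton", e_p,
          w_p / w_p.sum(),
          "synthetic recoil-proton spectrum (epithermal-beam-like stand-in)")

    e_e = np.geomspace(0.003, 1.5, 40)
    w_e = e_e**-0.3 * np.exp(-e_e / 0.35)
    write(OUT / "spectrum_photon_electrons_synthetic.tsv", "electron", e_e,
          w_e / w_e.sum(),
          "synthetic secondary-electron spectrum (Compton-like stand-in)")


if __name__ == "__main__":
    main()
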