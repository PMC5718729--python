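"""Generate the packaged parametric kilovoltage data files:

- src/ctdose/data/materials_mu.csv : mass attenuation coefficients on a
  10-150 keV log grid; incoherent from the Klein-Nishina cross-section,
  photoelectric and coherent as power-law fits anchored at 30 keV.
- src/ctdose/data/spectrum_120kvp.csv : filtered Kramers 120 kVp tungsten
  spectrum with K characteristic lines.
"""
import numpy as np
from pathlib import Path

R_E = 2.8179403262e-13  # cm
MEC2 = 511.0  # keV


def sigma_kn(e_keV):
    a = np.asarray(e_keV, float) / MEC2
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * R_E**2 * (t1 + t2 - t3)


# electrons per gram; PE and coherent mu/rho anchors at 30 keV (cm^2/g)
MATERIALS = {
    # name: (e_per_g, pe30, ray30)
    "air": (3.006e23, 0.146, 0.0437),
    "lung": (3.343e23, 0.149, 0.0442),
    "soft_tissue": (3.343e23, 0.149, 0.0442),
    "bone": (3.100e23, 0.870, 0.0957),
    "aluminum": (2.902e23, 0.870, 0.0880),
}
PE_EXP = -3.05
RAY_EXP = -1.90

egrid = np.round(np.logspace(np.log10(10.0), np.log10(150.0), 30), 4)

datadir = Path(__file__).resolve().parents[1] / "src" / "ctdose" / "data"
datadir.mkdir(parents=True, exist_ok=True)

lines = [
    "# Synthetic parametric mass attenuation coefficients (cm^2/g) for",
    "# kilovoltage photon transport. Incoherent (Compton) computed from the",
    "# Klein-Nishina cross-section times electrons per gram; photoelectric",
    "# and coherent (Rayleigh) are power-law fits anchored at 30 keV to",
    "# standard tabulated values. Not a NIST extract.",
    "material,energy_keV,mu_rho_photoelectric,mu_rho_compton,mu_rho_rayleigh",
]
for name, (epg, pe30, ray30) in MATERIALS.items():
    compton = sigma_kn(egrid) * epg
    pe = pe30 * (egrid / 30.0) ** PE_EXP
    ray = ray30 * (egrid / 30.0) ** RAY_EXP
    for e, p, c, r in zip(egrid, pe, compton, ray):
        lines.append(f"{name},{e:.4f},{p:.6e},{c:.6e},{r:.6e}")
(datadir / "materials_mu.csv").write_text("\n".join(lines) + "\n")

# aluminum total at 60 keV (used as the effective bowtie attenuation const)
al = MATERIALS["aluminum"]
al_tot60 = (sigma_kn(60.0) * al[0] + al[1] * 2 ** PE_EXP + al[2] * 2 ** RAY_EXP)
print(f"aluminum mu/rho @60 keV = {al_tot60:.5f} cm^2/g -> mu = "
      f"{al_tot60 * 2.699 / 10:.5f} /mm")
w = MATERIALS["soft_tissue"]
w_tot60 = sigma_kn(60.0) * w[0] + w[1] * 2 ** PE_EXP + w[2] * 2 ** RAY_EXP
print(f"water-like mu/rho @60 keV = {w_tot60:.5f} cm^2/g")

# --- spectrum ---------------------------------------------------------------
E0 = 120.0
es = np.arange(10.0, E0 + 0.5, 2.0)
kramers = np.clip(E0 - es, 0, None) / es
altab = {"e": egrid,
         "mu": sigma_kn(egrid) * al[0] + al[1] * (egrid / 30) ** PE_EXP
               + al[2] * (egrid / 30) ** RAY_EXP}
mu_al = np.interp(es, altab["e"], altab["mu"])  # cm^2/g
t_filter_mm = 6.0  # equivalent-Al inherent + flat filtration
w = kramers * np.exp(-mu_al * 2.699 * t_filter_mm / 10.0)
# tungsten K lines (Ka ~58-59, Kb ~67-69 keV)
for e_line, frac in ((58.0, 0.05), (60.0, 0.03), (68.0, 0.025)):
    i = int(np.argmin(np.abs(es - e_line)))
    w[i] += frac * w.sum()
w = w / w.sum()
mean_e = float((w * es).sum())
print(f"spectrum mean energy = {mean_e:.2f} keV")

lines = [
    "# Synthetic parametric 120 kVp tungsten spectrum: Kramers bremsstrahlung",
    f"# filtered by {t_filter_mm} mm equivalent aluminum, with K lines added.",
    "# Weights are relative fluence per bin and sum to 1.",
    "energy_keV,weight",
]
lines += [f"{e:.1f},{x:.6e}" for e, x in zip(es, w)]
(datadir / "spectrum_120kvp.csv").write_text("\n".join(lines) + "\n")
print("wrote", datadir)
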