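# Bundled nuclide constants, version 1.
#
# mean_electron_MeV: mean energy per decay carried by beta particles plus
#   conversion/Auger electrons (deposited locally at PET voxel scales).
# mean_photon_MeV: mean energy per decay carried by gamma/X-ray photons;
#   ignored by the local engine and off by default in kernel mode.
# kernel_csv: radial electron dose-kernel profile bundled alongside.
version: 1
nuclides:
  lu177:
    half_life_days: 6.67
    mean_electron_MeV: 0.1479
    mean_photon_MeV: 0.0334
    kernel_csv: lu177_kernel.csv
  f18:
    half_life_days: 0.0762
    mean_electron_MeV: 0.2498
    mean_photon_MeV: 1.022
    kernel_csv: null
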