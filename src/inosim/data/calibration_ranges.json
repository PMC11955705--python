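{
  "version": "fixture-1",
  "description": "Healthy human left-ventricular biomarker acceptance intervals used to calibrate the surrogate population. Units: durations ms, voltages mV, dVdtmax mV/ms, calcium mM, tension kPa.",
  "ranges": {
    "APD40": [85, 320],
    "APD50": [110, 350],
    "APD90": [180, 440],
    "Tri90_40": [30, 150],
    "dVdtmax": [100, 1000],
    "Vpeak": [10, 55],
    "RMP": [-95, -80],
    "CTD50": [120, 420],
    "CTD90": [220, 785],
    "CTpeak": [1e-4, 2e-3],
    "CaiD": [2e-5, 3e-4],
    "ATpeak": [5, 60]
  }
}
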