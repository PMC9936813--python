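{
 "name": "olm-single reference",
 "capacitance_pF": 150.29999999999998,
 "bias_current_pA": 4.0,
 "area_cm2": 0.000167,
 "channels": [
  {
   "name": "leak",
   "gbar_uS": 0.00385,
   "erev_mV": -74.0,
   "gates": []
  },
  {
   "name": "Na",
   "gbar_uS": 0.80995,
   "erev_mV": 90.0,
   "gates": [
    {
     "name": "m",
     "power": 3,
     "steady_state": {
      "form": "boltzmann",
      "vhalf": -46.0,
      "k": -6.0
     },
     "time_constant": {
      "form": "gauss",
      "base": 0.1,
      "amp": 0.6,
      "vpeak": -38.0,
      "sigma": 20.0
     }
    },
    {
     "name": "h",
     "power": 1,
     "steady_state": {
      "form": "boltzmann",
      "vhalf": -52.0,
      "k": 5.0
     },
     "time_constant": {
      "form": "gauss",
      "base": 0.5,
      "amp": 8.0,
      "vpeak": -55.0,
      "sigma": 25.0
     }
    }
   ]
  },
  {
   "name": "Kdrf",
   "gbar_uS": 0.7231099999999998,
   "erev_mV": -96.0,
   "gates": [
    {
     "name": "n",
     "power": 4,
     "steady_state": {
      "form": "boltzmann",
      "vhalf": -26.0,
      "k": -6.0
     },
     "time_constant": {
      "form": "gauss",
      "base": 0.5,
      "amp": 2.5,
      "vpeak": -35.0,
      "sigma": 30.0
     }
    }
   ]
  },
  {
   "name": "Ka",
   "gbar_uS": 1.22077,
   "erev_mV": -96.0,
   "gates": [
    {
     "name": "a",
     "power": 1,
     "steady_state": {
      "form": "boltzmann",
      "vhalf": -25.0,
      "k": -6.0
     },
     "time_constant": {
      "form": "gauss",
      "base": 0.5,
      "amp": 4.0,
      "vpeak": -40.0,
      "sigma": 30.0
     }
    },
    {
     "name": "b",
     "power": 1,
     "steady_state": {
      "form": "boltzmann",
      "vhalf": -80.0,
      "k": 6.0
     },
     "time_constant": {
      "form": "gauss",
      "base": 25.0,
      "amp": 100.0,
      "vpeak": -80.0,
      "sigma": 30.0
     }
    }
   ]
  },
  {
   "name": "M",
   "gbar_uS": 0.0031896999999999997,
   "erev_mV": -96.0,
   "gates": [
    {
     "name": "z",
     "power": 1,
     "steady_state": {
      "form": "boltzmann",
      "vhalf": -37.0,
      "k": -5.0
     },
     "time_constant": {
      "form": "bell",
      "base": 30.0,
      "amp": 600.0,
      "vhalf": -38.0,
      "k1": 20.0,
      "k2": 20.0
     }
    }
   ]
  },
  {
   "name": "h",
   "gbar_uS": 0.0015,
   "erev_mV": -34.6,
   "gates": [
    {
     "name": "r",
     "power": 1,
     "steady_state": {
      "form": "boltzmann",
      "vhalf": -82.0,
      "k": 9.0
     },
     "time_constant": {
      "form": "gauss",
      "base": 60.0,
      "amp": 180.0,
      "vpeak": -90.0,
      "sigma": 30.0
     }
    }
   ]
  }
 ]
}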