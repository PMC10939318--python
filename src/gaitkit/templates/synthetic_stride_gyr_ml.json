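{"samples": [5.051575, 15.134789, 25.158273, 35.082469, 44.868211, 54.476878, 63.87055, 73.012153, 81.865612, 90.395984, 98.569604, 106.354215, 113.719095, 120.635177, 127.075168, 133.013651, 138.427189, 143.294419, 147.596132, 151.315349, 154.437394, 156.949946, 158.843087, 160.109348, 160.74373, 160.74373, 160.109348, 158.843087, 156.949946, 154.437394, 151.315349, 147.596132, 143.294419, 138.427189, 133.013651, 127.075168, 120.635177, 113.719095, 106.354215, 98.569604, 90.395984, 81.865612, 73.012153, 63.87055, 54.476878, 44.868211, 35.082469, 25.158273, 15.134789, 5.051575, -5.051575, -15.134789, -25.158273, -35.082469, -44.868211, -54.476878, -63.87055, -73.012153, -81.865612, -90.395984, -98.569604, -106.354215, -113.719095, -120.635177, -127.075168, -133.013651, -138.427189, -143.294419, -147.596132, -151.315349, -154.437394, -156.949946, -158.843087, -160.109348, -160.74373, -160.74373, -160.109348, -158.843087, -156.949946, -154.437394, -151.315349, -147.596132, -143.294419, -138.427189, -133.013651, -127.075168, -120.635177, -113.719095, -106.354215, -98.569604, -90.395984, -81.865612, -73.012153, -63.87055, -54.476878, -44.868211, -35.082469, -25.158273, -15.134789, -5.051575, -0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0], "sampling_rate_hz": 204.8, "scaling": 500.0, "provenance": "synthetic: one noise-free simulated stride (gyr_ml, toe-off to toe-off) from the package's gait simulator, default profile"}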