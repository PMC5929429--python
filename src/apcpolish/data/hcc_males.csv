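age,1976–1980,1981–1985,1986–1990,1991–1995,1996–2000,2001–2005,2006–2010
40–44,31.41,33.10,33.20,31.24,30.40,29.10,23.26
45–49,46.50,55.13,52.88,53.61,49.79,47.66,42.25
50–54,68.11,72.47,74.56,81.73,81.65,74.19,69.12
55–59,84.12,97.32,98.96,115.57,127.55,117.70,100.19
60–64,103.58,120.45,115.71,143.74,164.14,168.20,145.35
65–69,126.15,140.12,138.76,160.29,186.58,204.31,203.50
70–74,135.44,147.79,170.44,195.56,201.40,223.00,253.46
75–79,145.41,178.22,186.70,226.86,243.87,234.63,263.24
80–84,123.63,160.33,175.09,229.23,267.55,264.61,276.39
85+,133.97,232.56,212.33,227.57,248.07,292.51,272.51
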