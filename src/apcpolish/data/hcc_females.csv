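age,1976–1980,1981–1985,1986–1990,1991–1995,1996–2000,2001–2005,2006–2010
40–44,6.75,6.14,4.90,5.11,3.46,2.88,3.03
45–49,11.99,11.10,9.21,9.76,6.49,5.76,4.90
50–54,18.20,16.23,14.78,15.53,14.15,11.78,10.20
55–59,27.57,30.06,24.45,28.43,28.65,28.04,23.68
60–64,35.23,39.48,41.09,44.75,55.75,52.97,48.01
65–69,43.49,54.68,52.09,66.36,76.92,89.05,82.80
70–74,50.40,61.49,65.48,87.47,111.46,130.60,131.32
75–79,66.47,72.02,77.57,105.09,127.37,153.26,160.98
80–84,60.12,74.79,81.83,101.26,139.41,175.41,184.90
85+,54.22,82.91,71.93,103.98,132.42,169.12,196.03
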