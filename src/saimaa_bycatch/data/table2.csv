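year,est_bycatch,obs_bycatch,est_pups_born,est_all_deaths,est_other_deaths,est_survivors_15m,est_population,bycatch_rate
1991,9.7,3,31,16.6,6.8,11.4,189.7,0.44
1992,9.7,1,34,18.3,8.6,12.7,191.0,0.39
1993,13.0,9,36,20.0,7.0,14.0,193.5,0.46
1994,11.4,4,38,18.2,6.8,12.8,194.7,0.44
1995,10.4,4,39,21.2,10.9,14.8,197.8,0.36
1996,9.5,0,40,15.8,6.3,11.2,197.2,0.44
1997,15.7,7,44,24.6,8.9,17.4,202.9,0.45
1998,11.9,10,41,22.2,10.3,15.8,206.7,0.37
1999,10.7,2,42,23.7,13.0,16.3,210.8,0.34
2000,17.6,6,57,31.5,13.9,22.5,221.0,0.42
2001,16.3,4,56,27.4,11.1,19.6,227.8,0.43
2002,14.8,8,56,31.3,16.5,22.7,237.4,0.33
2003,16.2,8,51,27.1,10.9,19.9,243.7,0.42
2004,18.6,6,66,35.0,16.4,25.0,254.9,0.36
2005,15.7,5,51,26.7,11.0,20.3,260.8,0.41
2006,12.7,6,52,23.2,10.6,17.8,264.0,0.37
2007,12.7,6,55,26.1,13.4,20.9,270.1,0.32
2008,11.9,5,51,26.1,14.2,20.9,276.0,0.30
2009,9.5,6,44,20.5,11.0,17.5,278.2,0.31
2010,16.0,5,57,28.4,12.4,24.6,287.4,0.37
2011,13.0,4,57,24.8,11.8,21.2,292.8,0.34
2012,16.9,7,61,31.5,14.6,26.5,303.3,0.35
2013,13.7,7,62,27.9,14.2,23.1,309.9,0.31
2014,15.4,7,64,29.6,14.1,25.4,318.5,0.33
2015,15.7,5,71,33.7,18.0,28.3,329.6,0.31
2016,20.1,5,87,43.4,23.3,35.6,347.5,0.30
2017,17.7,7,83,37.3,19.6,30.7,359.7,0.31
2018,19.7,4,86,42.0,22.3,34.0,374.7,0.31
2019,22.7,6,88,46.8,24.1,40.2,395.2,0.33
2020,20.7,4,88,42.5,21.8,34.5,409.0,0.33
2021,15.9,2,90,45.2,29.3,33.8,421.6,0.24
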