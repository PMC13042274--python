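name,country,lat,lon,kind
Los Angeles,United States,34.05,-118.24,place
San Francisco,United States,37.7749,-122.4194,place
New York,United States,40.71,-74.01,place
Seattle,United States,47.61,-122.33,place
Honolulu,United States,21.31,-157.86,place
Vancouver,Canada,49.28,-123.12,place
Toronto,Canada,43.65,-79.38,place
Mexico City,Mexico,19.43,-99.13,place
Lima,Peru,-12.05,-77.04,place
Santiago,Chile,-33.45,-70.67,place
Buenos Aires,Argentina,-34.60,-58.38,place
Rio de Janeiro,Brazil,-22.91,-43.17,place
Manaus,Brazil,-3.12,-60.02,place
Reykjavik,Iceland,64.15,-21.94,place
Dublin,Ireland,53.35,-6.26,place
Lisbon,Portugal,38.72,-9.14,place
Madrid,Spain,40.42,-3.70,place
London,United Kingdom,51.51,-0.13,place
Paris,France,48.86,2.35,place
Zurich,Switzerland,47.37,8.55,place
Rome,Italy,41.90,12.50,place
Berlin,Germany,52.52,13.41,place
Oslo,Norway,59.91,10.75,place
Stockholm,Sweden,59.33,18.07,place
Helsinki,Finland,60.17,24.94,place
Athens,Greece,37.98,23.73,place
Cairo,Egypt,30.04,31.24,place
Nairobi,Kenya,-1.29,36.82,place
Cape Town,South Africa,-33.92,18.42,place
Lagos,Nigeria,6.52,3.38,place
Moscow,Russia,55.76,37.62,place
Istanbul,Turkey,41.01,28.98,place
Tehran,Iran,35.69,51.39,place
Dubai,United Arab Emirates,25.20,55.27,place
Mumbai,India,19.08,72.88,place
New Delhi,India,28.61,77.21,place
Kathmandu,Nepal,27.72,85.32,place
Bangkok,Thailand,13.76,100.50,place
Singapore,Singapore,1.35,103.82,place
Jakarta,Indonesia,-6.21,106.85,place
Hong Kong,China,22.32,114.17,place
Beijing,China,39.90,116.41,place
Shanghai,China,31.23,121.47,place
Seoul,South Korea,37.57,126.98,place
Tokyo,Japan,35.68,139.69,place
Darwin,Australia,-12.46,130.84,place
Perth,Australia,-31.95,115.86,place
Sydney,Australia,-33.87,151.21,place
Auckland,New Zealand,-36.85,174.76,place
McMurdo Station,Antarctica,-77.85,166.67,place
University of Zurich,Switzerland,47.3974,8.5486,institution
Massachusetts Institute of Technology,United States,42.3601,-71.0942,institution
Wageningen University,Netherlands,51.9854,5.6638,institution
University of Tokyo,Japan,35.7126,139.7620,institution
University of Queensland,Australia,-27.4975,153.0137,institution
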